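"""Reading, writing and validating the toolkit's tabular formats.

Formats
-------
Beta matrix
    Delimited text (comma or tab), header row, first column the probe ID
    (``cg…``), remaining columns samples; values are methylation fractions
    in [0, 1]; empty fields or ``NA`` are missing.  The transposed dialect
    (samples in rows) is accepted via ``dialect="samples_in_rows"``.
Sample annotation
    CSV with required columns ``sample_id`` and ``age`` (years, > -1;
    small negative values encode gestational offsets for cord blood) and
    optional ``sex``, ``tissue``, ``disease`` (``control`` reserved for
    reference samples) and ``pdl`` (cumulative population doublings >= 0).
Probe manifest
    One probe ID per line; represents the probe universe of one array
    platform (450K, EPIC, ...).
Clock coefficients
    CSV with columns ``term`` and ``coefficient``; one row's term is
    ``(Intercept)``.  This is the interchange format for externally
    published clocks; it carries no training means, so the resulting
    :class:`~dnamclock.model.ClockModel` is partial.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from dnamclock.model import ClockModel

logger = logging.getLogger(__name__)

__all__ = [
    "BetaMatrix",
    "ProbeManifest",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_annotation",
    "read_manifest",
    "intersect_platforms",
    "read_clock_coefficients",
    "write_coefficients",
]

_PROBE_RE = re.compile(r"^cg\d+$")
_NA_VALUES = ["", "NA", "NaN", "nan"]


@dataclass
class BetaMatrix:
    """Probes x samples matrix of methylation fractions.

    ``values`` is a float array of shape ``(len(probe_ids), len(sample_ids))``
    with ``NaN`` marking missing entries; all non-missing values lie in
    [0, 1].
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        for name, ids in (("probe", self.probe_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise ValueError(f"duplicate {name} identifiers: {dupes[:5]}")
        bad = np.where((self.values < 0) | (self.values > 1))
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            raise ValueError(
                f"beta value out of [0,1]: {self.values[i, j]} at probe "
                f"{self.probe_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )
        odd = [p for p in self.probe_ids if not _PROBE_RE.match(p)]
        if odd:
            logger.warning(
                "%d probe IDs do not match the 'cg<digits>' pattern (e.g. %r)",
                len(odd), odd[0],
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "BetaMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def subset_probes(self, probes) -> "BetaMatrix":
        """Restrict to the given probes, preserving this matrix's probe order."""
        keep = set(probes)
        idx = [i for i, p in enumerate(self.probe_ids) if p in keep]
        return BetaMatrix(
            [self.probe_ids[i] for i in idx], list(self.sample_ids), self.values[idx]
        )


@dataclass(frozen=True)
class ProbeManifest:
    """Probe universe of one array platform."""

    platform_name: str
    probe_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.probe_ids:
            raise ValueError(f"manifest {self.platform_name!r} has no probes")


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_beta_matrix(path, dialect: str = "probes_in_rows") -> BetaMatrix:
    """Read a delimited beta matrix; see module docstring for the format."""
    if dialect not in ("probes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        df = pd.read_csv(
            path, sep=None, engine="python", index_col=0,
            na_values=_NA_VALUES, keep_default_na=False,
        )
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"malformed beta matrix {path}: {exc}") from exc
    if dialect == "samples_in_rows":
        df = df.T
    df.index = df.index.astype(str)
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric beta value in {path}: {exc}") from exc
    return BetaMatrix(list(df.index), [str(c) for c in df.columns], values)


def write_beta_matrix(m: BetaMatrix, path, dialect: str = "probes_in_rows") -> None:
    df = m.to_dataframe()
    if dialect == "samples_in_rows":
        df = df.T
    df.to_csv(path, sep=_sep_for(path), index_label="probe_id", na_rep="NA")


def read_sample_annotation(path) -> pd.DataFrame:
    """Read and validate a sample annotation table.

    Returns a DataFrame with columns sample_id, age, sex, tissue, disease,
    pdl (absent optional columns filled with defaults: sex ``unknown``,
    tissue ``unknown``, disease ``control``, pdl ``NaN``).
    """
    df = pd.read_csv(path, sep=None, engine="python", na_values=_NA_VALUES,
                     keep_default_na=False)
    return validate_annotation(df)


def validate_annotation(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in ("sample_id", "age"):
        if col not in df.columns:
            raise ValueError(f"annotation is missing required column {col!r}")
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id values: {dupes[:5]}")
    df["age"] = df["age"].astype(float)
    bad = df.loc[~(df["age"] > -1) | ~np.isfinite(df["age"]), "sample_id"]
    if len(bad):
        raise ValueError(f"age must be finite and > -1; offending samples: {list(bad[:5])}")
    for col, default in (("sex", "unknown"), ("tissue", "unknown"), ("disease", "control")):
        if col not in df.columns:
            df[col] = default
        df[col] = df[col].fillna(default).astype(str)
    if "pdl" not in df.columns:
        df["pdl"] = np.nan
    df["pdl"] = df["pdl"].astype(float)
    present = df["pdl"].notna()
    if ((df.loc[present, "pdl"] < 0) | ~np.isfinite(df.loc[present, "pdl"])).any():
        raise ValueError("pdl values must be finite and >= 0 when present")
    return df[["sample_id", "age", "sex", "tissue", "disease", "pdl"]]


def read_manifest(path, platform_name: str | None = None) -> ProbeManifest:
    """Read a one-probe-per-line platform manifest."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    probes = [ln for ln in lines if ln]
    if len(set(probes)) != len(probes):
        raise ValueError(f"manifest {path} contains duplicate probe IDs")
    return ProbeManifest(platform_name or Path(path).stem, frozenset(probes))


def intersect_platforms(m: BetaMatrix, manifests) -> BetaMatrix:
    """Restrict a beta matrix to probes present on every platform.

    Probe order is preserved from ``m``.  The result is the matrix of
    probes usable by a cross-platform clock.
    """
    manifests = list(manifests)
    if not manifests:
        raise ValueError("at least one manifest is required")
    keep = set(m.probe_ids)
    for man in manifests:
        keep &= set(man.probe_ids)
    if not keep:
        names = [man.platform_name for man in manifests]
        raise ValueError(
            f"no probes shared between the matrix and manifests {names}; "
            "check that manifests use the same probe-ID convention"
        )
    return m.subset_probes(keep)


_INTERCEPT_LABELS = {"(intercept)", "intercept"}


def read_clock_coefficients(path) -> ClockModel:
    """Load an externally supplied coefficient table as a partial clock.

    The file must have columns ``term`` and ``coefficient`` with exactly one
    intercept row.  The returned model has no training probe means; missing
    probes cannot be imputed when applying it.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower(): c for c in df.columns}
    if "term" not in cols or "coefficient" not in cols:
        raise ValueError(f"coefficient file {path} needs columns 'term' and 'coefficient'")
    terms = df[cols["term"]].astype(str)
    coefs = df[cols["coefficient"]].astype(float)
    is_int = terms.str.lower().isin(_INTERCEPT_LABELS)
    if is_int.sum() != 1:
        raise ValueError(
            f"coefficient file {path} must contain exactly one intercept row "
            f"(found {int(is_int.sum())})"
        )
    probes = terms[~is_int]
    if probes.duplicated().any():
        dupes = probes[probes.duplicated()].tolist()
        raise ValueError(f"duplicate probe rows in {path}: {dupes[:5]}")
    weights = dict(zip(probes, coefs[~is_int]))
    model = ClockModel(intercept=float(coefs[is_int].iloc[0]), weights=weights)
    logger.info("loaded clock with %d probe weights from %s", len(weights), path)
    return model


def write_coefficients(model: ClockModel, path) -> None:
    """Write a model's intercept and probe weights as a two-column CSV."""
    rows = [("(Intercept)", model.intercept)]
    rows += sorted(model.weights.items())
    pd.DataFrame(rows, columns=["term", "coefficient"]).to_csv(path, index=False)
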