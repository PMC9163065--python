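"""Core array domain model: probe manifests, beta-value matrices, sample
sheets, detection-p QC filtering and per-sample beta summaries.

Conventions
-----------
* beta values are methylated-signal fractions in [0, 1]; missing values are
  carried as NaN in memory and written as ``NA`` on disk.
* Probe coordinates are 1-based point positions (Illumina manifest style);
  the optional BED export converts them to 0-based half-open intervals.
* Quantiles use linear interpolation between order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyDataError,
    FormatError,
    SampleLookupError,
    ValidationError,
)

#: Allowed chromosome labels, in canonical karyotype order.
CHROMOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX", "chrY")

#: Genomic-context vocabulary for EPIC-style annotations.
GENOMIC_CONTEXTS: frozenset[str] = frozenset(
    {"TSS200", "TSS1500", "5UTR", "body", "3UTR", "intergenic"}
)

#: Contexts treated as promoter-proximal. Mirrors common Infinium annotation
#: practice (TSS200/TSS1500/5'UTR); configurable via ``read_manifest``.
PROMOTER_CONTEXTS: frozenset[str] = frozenset({"TSS200", "TSS1500", "5UTR"})

STRANDS: frozenset[str] = frozenset({"+", "-", "unknown"})

SAMPLE_GROUPS: frozenset[str] = frozenset(
    {"parental", "resistant", "dko", "normal_tissue", "tumor", "adjacent_normal"}
)

SEXES: frozenset[str] = frozenset({"male", "female"})

MISSING_SENTINEL = "NA"


def chromosome_sort_key(label: str) -> int:
    """Karyotype order index for a chromosome label (chr1 < ... < chrX < chrY)."""
    try:
        return CHROMOSOMES.index(label)
    except ValueError:
        raise ValidationError(f"unknown chromosome label: {label!r}") from None


class BetaMatrix:
    """Probes x samples methylation-fraction matrix with NaN as missing marker.

    Thin wrapper over a float ``pandas.DataFrame`` (index = probe ids,
    columns = sample ids) that enforces the [0, 1] range and unique ids.
    """

    def __init__(self, values: pd.DataFrame, *, validate: bool = True):
        values = values.astype(float)
        if validate:
            self._validate(values)
        self.values = values

    @staticmethod
    def _validate(values: pd.DataFrame) -> None:
        if values.index.has_duplicates:
            dup = values.index[values.index.duplicated()][0]
            raise ValidationError(f"duplicate probe_id in beta matrix: {dup!r}")
        if values.columns.has_duplicates:
            dup = values.columns[values.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample_id in beta matrix: {dup!r}")
        arr = values.to_numpy()
        bad = (arr < 0.0) | (arr > 1.0)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"beta value out of [0,1] at probe {values.index[i]!r}, "
                f"sample {values.columns[j]!r}: {arr[i, j]}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def sample(self, sample_id: str) -> pd.Series:
        """Column of beta values for one sample (NaN = missing)."""
        if sample_id not in self.values.columns:
            raise SampleLookupError(f"unknown sample id: {sample_id!r}")
        return self.values[sample_id]

    def subset_probes(self, probe_ids: Iterable[str]) -> "BetaMatrix":
        idx = pd.Index(probe_ids)
        missing = idx.difference(self.values.index)
        if len(missing):
            raise ValidationError(f"probes absent from matrix: {list(missing[:5])}")
        return BetaMatrix(self.values.loc[idx], validate=False)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"BetaMatrix({self.n_probes} probes x {self.n_samples} samples)"


@dataclass(frozen=True)
class BetaSummary:
    """Order statistics of one sample's non-missing beta values.

    Matches the usual box-plot summary: quartile box, median line and
    5/95-percentile whiskers.
    """

    sample_id: str
    mean: float
    median: float
    q25: float
    q75: float
    p5: float
    p95: float
    n_probes_used: int

    def __post_init__(self) -> None:
        chain = (self.p5, self.q25, self.median, self.q75, self.p95)
        if not all(a <= b for a, b in zip(chain, chain[1:])):
            raise ValidationError(f"order statistics out of order: {chain}")
        if not all(0.0 <= v <= 1.0 for v in chain):
            raise ValidationError(f"summary statistic outside [0,1]: {chain}")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_MANIFEST_REQUIRED = ("probe_id", "chromosome", "position", "genomic_context")


def read_manifest(
    path: str | Path,
    *,
    promoter_contexts: frozenset[str] = PROMOTER_CONTEXTS,
) -> pd.DataFrame:
    """Read a probe manifest CSV into a validated annotation table.

    Returns a DataFrame indexed by ``probe_id`` with columns ``chromosome``,
    ``position``, ``genomic_context``, ``strand`` and the derived
    ``is_promoter`` flag (true iff the context is in *promoter_contexts*).
    """
    df = pd.read_csv(path, dtype=str)
    for col in _MANIFEST_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"manifest is missing required column {col!r}")
    if "strand" not in df.columns:
        df["strand"] = "unknown"
    df["strand"] = df["strand"].fillna("unknown")
    return validate_manifest(
        df[["probe_id", "chromosome", "position", "genomic_context", "strand"]],
        promoter_contexts=promoter_contexts,
    )


def validate_manifest(
    df: pd.DataFrame,
    *,
    promoter_contexts: frozenset[str] = PROMOTER_CONTEXTS,
) -> pd.DataFrame:
    """Validate manifest columns and derive ``is_promoter``; returns indexed copy."""
    df = df.copy()
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ValidationError(f"duplicate probe_id in manifest: {dup!r}")
    bad_chrom = set(df["chromosome"]) - set(CHROMOSOMES)
    if bad_chrom:
        raise ValidationError(f"unknown chromosome labels: {sorted(bad_chrom)}")
    try:
        df["position"] = df["position"].astype(int)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-integer probe position: {exc}") from exc
    if (df["position"] < 1).any():
        bad = df.loc[df["position"] < 1].iloc[0]
        raise ValidationError(
            f"position must be >= 1 (1-based); probe {bad['probe_id']!r} has {bad['position']}"
        )
    bad_ctx = set(df["genomic_context"]) - GENOMIC_CONTEXTS
    if bad_ctx:
        raise ValidationError(f"unknown genomic_context labels: {sorted(bad_ctx)}")
    bad_strand = set(df["strand"]) - STRANDS
    if bad_strand:
        raise ValidationError(f"unknown strand labels: {sorted(bad_strand)}")
    df["is_promoter"] = df["genomic_context"].isin(promoter_contexts)
    return df.set_index("probe_id")


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    out = manifest.reset_index()[
        ["probe_id", "chromosome", "position", "genomic_context", "strand"]
    ]
    out.to_csv(path, index=False)


def read_beta_matrix(path: str | Path) -> BetaMatrix:
    """Read a probes-x-samples TSV (first column probe_id, ``NA`` = missing)."""
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=[MISSING_SENTINEL, ""], comment="#"
    )
    if df.shape[1] == 0:
        raise FormatError(f"beta matrix {path} has no sample columns")
    try:
        return BetaMatrix(df)
    except ValidationError:
        raise
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric cell in beta matrix {path}: {exc}") from exc


def write_beta_matrix(
    betas: BetaMatrix, path: str | Path, *, float_format: str = "%.6g"
) -> None:
    betas.values.to_csv(
        path, sep="\t", na_rep=MISSING_SENTINEL, float_format=float_format,
        index_label="probe_id",
    )


_SAMPLE_REQUIRED = ("sample_id", "group", "sex", "tissue")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    for col in _SAMPLE_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"sample sheet is missing required column {col!r}")
    return validate_sample_sheet(df[list(_SAMPLE_REQUIRED)])


def validate_sample_sheet(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"duplicate sample_id in sample sheet: {dup!r}")
    bad_group = set(df["group"]) - SAMPLE_GROUPS
    if bad_group:
        raise ValidationError(f"unknown sample group labels: {sorted(bad_group)}")
    bad_sex = set(df["sex"]) - SEXES
    if bad_sex:
        raise ValidationError(f"unknown sex labels: {sorted(bad_sex)}")
    return df.set_index("sample_id")


def write_sample_sheet(samples: pd.DataFrame, path: str | Path) -> None:
    samples.reset_index().to_csv(path, index=False)


def write_probe_bed(
    manifest: pd.DataFrame, probe_ids: Sequence[str], path: str | Path
) -> None:
    """Export probes as BED intervals ([pos-1, pos), 0-based half-open)."""
    sub = manifest.loc[pd.Index(probe_ids)]
    bed = pd.DataFrame(
        {
            "chrom": sub["chromosome"],
            "start": sub["position"] - 1,
            "end": sub["position"],
            "name": sub.index,
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# QC and summaries
# ---------------------------------------------------------------------------


def apply_detection_filter(
    betas: BetaMatrix,
    detection_p: BetaMatrix | pd.DataFrame,
    threshold: float = 0.05,
) -> tuple[BetaMatrix, int]:
    """Drop probes whose detection p-value exceeds *threshold* in any sample.

    A probe survives only when its detection p is <= *threshold* in every
    sample, i.e. the beta value is reliable across the whole panel. Returns
    the filtered matrix (probe order preserved) and the number removed.
    """
    if not 0.0 < threshold < 1.0:
        raise ValidationError(f"detection threshold must be in (0,1), got {threshold}")
    detp = detection_p.values if isinstance(detection_p, BetaMatrix) else detection_p
    if detp.shape != betas.values.shape:
        raise ValidationError(
            f"detection-p shape {detp.shape} != beta shape {betas.values.shape}"
        )
    if not detp.index.equals(betas.probe_ids) or not detp.columns.equals(
        betas.sample_ids
    ):
        raise ValidationError("detection-p probe/sample ids do not match beta matrix")
    keep = (detp.to_numpy() <= threshold).all(axis=1)
    filtered = BetaMatrix(betas.values.loc[keep], validate=False)
    return filtered, int((~keep).sum())


def summarize_beta(betas: BetaMatrix, sample_id: str) -> BetaSummary:
    """Box-plot summary (mean, median, quartiles, 5/95 percentiles) for a sample."""
    col = betas.sample(sample_id).dropna()
    if col.empty:
        raise EmptyDataError(f"sample {sample_id!r} has no non-missing beta values")
    vals = col.to_numpy()
    p5, q25, med, q75, p95 = np.percentile(vals, [5, 25, 50, 75, 95])
    return BetaSummary(
        sample_id=sample_id,
        mean=float(vals.mean()),
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        p5=float(p5),
        p95=float(p95),
        n_probes_used=int(vals.size),
    )
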