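"""Classification of demethylation-resistant promoter probes by their
methylation status in non-cancer tissues.

A probe that stays highly methylated (beta >= 0.7) in both the parental
and the DNMT1-inhibited cell line either (a) was already methylated in
non-cancer tissue (constitutive methylation) or (b) acquired its
methylation de novo in the cancer line. The two are separated by the
per-sex mean beta across a panel of non-cancer tissue samples:

* methylated_in_normal: mean beta >= 0.7 in both sexes;
* unmethylated_in_normal (de novo in cancer):
  - autosomes: mean beta <= t_low in both sexes;
  - chrX: male mean <= t_low (single active X unmethylated) and female
    mean either <= t_low (site escapes X inactivation) or inside the
    monoallelic band around 0.5 (site subject to X inactivation, one
    methylated inactive X);
* anything else: unclassified.

Default thresholds: t_low = 0.3, monoallelic band [0.3, 0.7],
methylated >= 0.7. The methylated rule takes precedence at band edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arrays import BetaMatrix
from .errors import EmptyDataError, ValidationError

DE_NOVO = "unmethylated_in_normal"
METHYLATED_NORMAL = "methylated_in_normal"
UNCLASSIFIED = "unclassified"

DEFAULT_CUTOFF = 0.7


@dataclass(frozen=True)
class ClassificationThresholds:
    """Numeric bounds behind the verbal categories; all configurable."""

    t_low: float = 0.3            # "unmethylated" upper bound
    mono_low: float = 0.3         # female monoallelic band (chrX, ~0.5)
    mono_high: float = 0.7
    t_high: float = 0.7           # "methylated" lower bound

    def __post_init__(self) -> None:
        vals = (self.t_low, self.mono_low, self.mono_high, self.t_high)
        if not all(0.0 <= v <= 1.0 for v in vals):
            raise ValidationError(f"thresholds must be in [0,1]: {vals}")
        if self.mono_low > self.mono_high:
            raise ValidationError("mono_low must be <= mono_high")


def select_retained_promoter_probes(
    betas: BetaMatrix,
    manifest: pd.DataFrame,
    parental_id: str,
    resistant_id: str,
    cutoff: float = DEFAULT_CUTOFF,
) -> pd.Index:
    """Promoter probes with beta >= cutoff in BOTH parental and resistant."""
    from .retention import call_high

    high_both = call_high(betas, parental_id, cutoff) & call_high(
        betas, resistant_id, cutoff
    )
    promoter = manifest.loc[betas.probe_ids, "is_promoter"].to_numpy()
    return betas.probe_ids[high_both.to_numpy() & promoter]


def classify_probe(
    male_mean: float,
    female_mean: float,
    parental_beta: float,
    resistant_beta: float,
    chromosome: str,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
    cutoff: float = DEFAULT_CUTOFF,
) -> str:
    """Category for a single probe given its per-sex normal-tissue means."""
    t = thresholds
    if np.isnan(parental_beta) or np.isnan(resistant_beta):
        return UNCLASSIFIED
    if parental_beta < cutoff or resistant_beta < cutoff:
        return UNCLASSIFIED
    if np.isnan(male_mean) or np.isnan(female_mean):
        return UNCLASSIFIED
    if male_mean >= t.t_high and female_mean >= t.t_high:
        return METHYLATED_NORMAL
    if chromosome == "chrX":
        female_ok = female_mean <= t.t_low or (
            t.mono_low <= female_mean <= t.mono_high
        )
        if male_mean <= t.t_low and female_ok:
            return DE_NOVO
    else:
        if male_mean <= t.t_low and female_mean <= t.t_low:
            return DE_NOVO
    return UNCLASSIFIED


def classify_probes(
    betas: BetaMatrix,
    manifest: pd.DataFrame,
    samples: pd.DataFrame,
    parental_id: str,
    resistant_id: str,
    cutoff: float = DEFAULT_CUTOFF,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> pd.DataFrame:
    """Classify every retained promoter probe against the normal-tissue panel.

    Normal-tissue evidence is the per-sex mean beta over the sample sheet's
    ``normal_tissue`` group (missing values excluded pairwise). Returns one
    row per selected probe: probe_id (index), chromosome, position,
    category, male_mean, female_mean, parental_beta, resistant_beta.
    """
    normals = samples[samples["group"] == "normal_tissue"]
    male_ids = normals.index[normals["sex"] == "male"]
    female_ids = normals.index[normals["sex"] == "female"]
    if male_ids.empty or female_ids.empty:
        raise EmptyDataError(
            "classification requires >= 1 male and >= 1 female normal_tissue sample"
        )
    probes = select_retained_promoter_probes(
        betas, manifest, parental_id, resistant_id, cutoff
    )
    sub = betas.values.loc[probes]
    male_mean = sub[male_ids].mean(axis=1, skipna=True)
    female_mean = sub[female_ids].mean(axis=1, skipna=True)
    chrom = manifest.loc[probes, "chromosome"]
    parental = sub[parental_id]
    resistant = sub[resistant_id]
    categories = [
        classify_probe(mm, fm, pb, rb, c, thresholds, cutoff)
        for mm, fm, pb, rb, c in zip(male_mean, female_mean, parental, resistant, chrom)
    ]
    return pd.DataFrame(
        {
            "chromosome": chrom,
            "position": manifest.loc[probes, "position"],
            "category": categories,
            "male_mean": male_mean,
            "female_mean": female_mean,
            "parental_beta": parental,
            "resistant_beta": resistant,
        },
        index=probes,
    )


@dataclass(frozen=True)
class ClassificationSummary:
    """Category counts over classified probes, genome-wide or chrX-only.

    ``pct_de_novo`` is the percentage of de novo (unmethylated-in-normal)
    probes among classified probes (unclassified excluded from the
    denominator).
    """

    scope: str
    n_total: int
    n_de_novo: int
    n_methylated_normal: int
    n_unclassified: int

    @property
    def pct_de_novo(self) -> float:
        denom = self.n_de_novo + self.n_methylated_normal
        if denom == 0:
            return float("nan")
        return 100.0 * self.n_de_novo / denom


def classification_summary(calls: pd.DataFrame, scope: str = "genome_wide") -> ClassificationSummary:
    """Summarize category counts, genome-wide or restricted to chrX."""
    if calls.empty:
        raise EmptyDataError("no probe calls to summarize")
    if scope == "chrX_only":
        calls = calls[calls["chromosome"] == "chrX"]
    elif scope != "genome_wide":
        raise ValidationError(f"unknown scope {scope!r}")
    counts = calls["category"].value_counts()
    return ClassificationSummary(
        scope=scope,
        n_total=int(len(calls)),
        n_de_novo=int(counts.get(DE_NOVO, 0)),
        n_methylated_normal=int(counts.get(METHYLATED_NORMAL, 0)),
        n_unclassified=int(counts.get(UNCLASSIFIED, 0)),
    )


def de_novo_chromosome_share(calls: pd.DataFrame, chromosome: str = "chrX") -> float:
    """Percent of all de novo probes located on *chromosome*.

    E.g. the share of genome-wide cancer-acquired promoter methylation that
    sits on the (single active) X chromosome.
    """
    de_novo = calls[calls["category"] == DE_NOVO]
    if de_novo.empty:
        return float("nan")
    return 100.0 * (de_novo["chromosome"] == chromosome).mean()


def locus_profile(
    betas: BetaMatrix,
    manifest: pd.DataFrame,
    chromosome: str,
    start: int,
    end: int,
    sample_groups: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Beta values for all probes in a genomic window, ordered by position.

    Coordinates are 1-based inclusive; a reversed (end < start) interval is
    normalized. When *sample_groups* maps group labels to sample-id lists,
    per-group mean columns (``mean_<group>``) are appended.
    """
    lo, hi = (start, end) if start <= end else (end, start)
    in_region = (
        (manifest["chromosome"] == chromosome)
        & (manifest["position"] >= lo)
        & (manifest["position"] <= hi)
    )
    region = manifest[in_region].sort_values(["position"], kind="mergesort")
    region = region[region.index.isin(betas.probe_ids)]
    out = betas.values.loc[region.index].copy()
    out.insert(0, "position", region["position"])
    if sample_groups:
        for group, ids in sample_groups.items():
            out[f"mean_{group}"] = betas.values.loc[region.index, list(ids)].mean(
                axis=1, skipna=True
            )
    return out
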