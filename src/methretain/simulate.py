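"""Synthetic EPIC-like methylome generator.

Emulates the statistical structure the downstream analyses assume:

* bimodal parental beta distributions (unmethylated and methylated modes),
  with ~60% of probes highly methylated on every chromosome in parental
  cancer cells;
* global demethylation in DNMT1-compromised lines with chromosome-specific
  retention probabilities (chrX strongly enriched; chr16/17/19/22 depleted),
  plus an intermediate "shoulder" component in drug-resistant (but not
  genetic-knockout) lines;
* sex-specific non-cancer tissue patterns on chrX: unmethylated in males,
  monoallelic (~0.5) in females at X-inactivated sites;
* tumor cohorts with per-probe de novo hypermethylation penetrance and
  sex-matched adjacent normals.

All draws come from a single ``numpy`` Generator seeded once; samples are
generated in a fixed documented order (parental, resistant, dko, normal
males, normal females, tumors, adjacent normals) so output is bit-identical
across runs and platforms for a given config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .arrays import (
    CHROMOSOMES,
    BetaMatrix,
    validate_manifest,
    validate_sample_sheet,
    write_beta_matrix,
    write_manifest,
    write_sample_sheet,
)
from .errors import ConfigError

NORMAL_STATES = ("normal_unmethylated", "normal_methylated", "x_inactivation_pattern")
CANCER_STATES = ("de_novo_methylated", "stays_unmethylated", "stays_methylated")

_PROMOTER_CONTEXTS = ("TSS200", "TSS1500", "5UTR")
_NON_PROMOTER_CONTEXTS = ("body", "3UTR", "intergenic")


def default_probe_counts() -> dict[str, int]:
    """Desk-scale probe counts (~20k total) roughly proportional to EPIC."""
    return {
        "chr1": 1700, "chr2": 1400, "chr3": 1050, "chr4": 850, "chr5": 980,
        "chr6": 1150, "chr7": 980, "chr8": 810, "chr9": 680, "chr10": 850,
        "chr11": 990, "chr12": 880, "chr13": 470, "chr14": 590, "chr15": 610,
        "chr16": 760, "chr17": 930, "chr18": 420, "chr19": 810, "chr20": 540,
        "chr21": 270, "chr22": 420, "chrX": 480, "chrY": 40,
    }


def default_retention_prob() -> dict[str, float]:
    """Retention probability of parental-high probes after DNMT1 loss.

    chrX is strongly enriched; the chromosomes observed to be selected
    against (19, 22, 17, 16) sit below the autosomal baseline.
    """
    probs = {c: 0.05 for c in CHROMOSOMES}
    probs["chrX"] = 0.25
    for c in ("chr16", "chr17", "chr19", "chr22"):
        probs[c] = 0.02
    return probs


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic methylome.

    Beta values are drawn from two-parameter Beta components:
    low (2,18) mean 0.1 for unmethylated, high (18,2) mean 0.9 for
    methylated, mono (12,12) mean 0.5 for the female X monoallelic state,
    and a mid (6,6) "shoulder" hit with probability
    ``intermediate_shoulder_prob`` by demethylated probes in drug-resistant
    lines only.
    """

    seed: int = 0
    probes_per_chromosome: Mapping[str, int] = field(default_factory=default_probe_counts)
    promoter_fraction: float = 0.25
    parental_methylated_fraction: float = 0.6
    retention_prob: Mapping[str, float] = field(default_factory=default_retention_prob)
    beta_shape_low: tuple[float, float] = (2.0, 18.0)
    beta_shape_high: tuple[float, float] = (18.0, 2.0)
    beta_shape_mono: tuple[float, float] = (12.0, 12.0)
    beta_shape_mid: tuple[float, float] = (6.0, 6.0)
    intermediate_shoulder_prob: float = 0.15
    # latent normal-tissue structure
    x_inactivation_fraction: float = 0.7   # chrX probes subject to XCI
    normal_methylated_fraction: float = 0.75  # probes methylated in normal tissue
    tumor_penetrance: float = 0.7   # per-tumor probability of de novo methylation
    n_normal_male: int = 3
    n_normal_female: int = 3
    n_tumor: int = 8
    n_adjacent: int = 4

    def validate(self) -> None:
        if not self.probes_per_chromosome:
            raise ConfigError("probes_per_chromosome must not be empty")
        unknown = set(self.probes_per_chromosome) - set(CHROMOSOMES)
        if unknown:
            raise ConfigError(f"unknown chromosomes in config: {sorted(unknown)}")
        if any(v < 0 for v in self.probes_per_chromosome.values()):
            raise ConfigError("probe counts must be >= 0")
        fracs = {
            "promoter_fraction": self.promoter_fraction,
            "parental_methylated_fraction": self.parental_methylated_fraction,
            "intermediate_shoulder_prob": self.intermediate_shoulder_prob,
            "x_inactivation_fraction": self.x_inactivation_fraction,
            "normal_methylated_fraction": self.normal_methylated_fraction,
            "tumor_penetrance": self.tumor_penetrance,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        for c, p in self.retention_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"retention_prob[{c}] must be in [0,1], got {p}")
        for name in ("beta_shape_low", "beta_shape_high", "beta_shape_mono", "beta_shape_mid"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise ConfigError(f"{name} parameters must be > 0, got ({a}, {b})")
        for name in ("n_normal_male", "n_normal_female", "n_tumor", "n_adjacent"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


@dataclass
class SimulatedDataset:
    """Bundle returned by :func:`simulate_dataset`."""

    manifest: pd.DataFrame          # probe annotations, indexed by probe_id
    betas: BetaMatrix               # all samples
    samples: pd.DataFrame           # sample sheet, indexed by sample_id
    truth: pd.DataFrame             # per-probe latent states, indexed by probe_id

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_manifest(self.manifest, outdir / "manifest.csv")
        write_beta_matrix(self.betas, outdir / "betas.tsv")
        write_sample_sheet(self.samples, outdir / "samples.csv")
        self.truth.reset_index().to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------


def _component_draws(rng: np.random.Generator, cfg: SimulationConfig, n: int):
    """One full set of component draws for one sample (fixed rng order)."""
    low = rng.beta(*cfg.beta_shape_low, size=n)
    high = rng.beta(*cfg.beta_shape_high, size=n)
    mono = rng.beta(*cfg.beta_shape_mono, size=n)
    mid = rng.beta(*cfg.beta_shape_mid, size=n)
    return low, high, mono, mid


def _normal_tissue_column(
    rng: np.random.Generator, cfg: SimulationConfig, truth: pd.DataFrame, sex: str
) -> np.ndarray:
    """Beta values for one non-cancer tissue sample of the given sex."""
    n = len(truth)
    low, high, mono, _ = _component_draws(rng, cfg, n)
    state = truth["normal_state"].to_numpy()
    col = low.copy()
    col[state == "normal_methylated"] = high[state == "normal_methylated"]
    xci = state == "x_inactivation_pattern"
    if sex == "female":
        col[xci] = mono[xci]
    # males: XCI sites are unmethylated on the single active X -> keep low
    return col


def _build_manifest(rng: np.random.Generator, cfg: SimulationConfig) -> pd.DataFrame:
    rows = []
    for chrom in CHROMOSOMES:
        count = int(cfg.probes_per_chromosome.get(chrom, 0))
        if count == 0:
            continue
        # sorted unique positions spread over a pseudo-chromosome
        positions = np.sort(
            rng.choice(np.arange(1, count * 1000 + 1), size=count, replace=False)
        )
        is_prom = rng.random(count) < cfg.promoter_fraction
        ctx_prom = rng.choice(_PROMOTER_CONTEXTS, size=count)
        ctx_other = rng.choice(_NON_PROMOTER_CONTEXTS, size=count)
        contexts = np.where(is_prom, ctx_prom, ctx_other)
        strands = rng.choice(["+", "-"], size=count)
        for i in range(count):
            rows.append(
                (f"cg_{chrom[3:]}_{i:06d}", chrom, int(positions[i]), contexts[i], strands[i])
            )
    if not rows:
        raise ConfigError("probes_per_chromosome yields zero probes")
    df = pd.DataFrame(
        rows, columns=["probe_id", "chromosome", "position", "genomic_context", "strand"]
    )
    return validate_manifest(df)


def _build_truth(
    rng: np.random.Generator, cfg: SimulationConfig, manifest: pd.DataFrame
) -> pd.DataFrame:
    n = len(manifest)
    chrom = manifest["chromosome"].to_numpy()

    # latent normal-tissue state
    normal_state = np.where(
        rng.random(n) < cfg.normal_methylated_fraction,
        "normal_methylated",
        "normal_unmethylated",
    ).astype(object)
    on_x = chrom == "chrX"
    xci_draw = rng.random(n) < cfg.x_inactivation_fraction
    normal_state[on_x & xci_draw] = "x_inactivation_pattern"

    # parental (cancer cell line) high-methylation flag, uniform per chromosome
    parental_high = rng.random(n) < cfg.parental_methylated_fraction

    # retention under DNMT1 compromise, chromosome-specific; only meaningful
    # for parental-high probes
    p_ret = np.array([cfg.retention_prob.get(c, 0.0) for c in chrom])
    retained = (rng.random(n) < p_ret) & parental_high

    cancer_state = np.full(n, "stays_unmethylated", dtype=object)
    cancer_state[parental_high & (normal_state == "normal_methylated")] = "stays_methylated"
    cancer_state[parental_high & (normal_state != "normal_methylated")] = "de_novo_methylated"

    return pd.DataFrame(
        {
            "normal_state": normal_state,
            "cancer_state": cancer_state,
            "parental_high": parental_high,
            "retained": retained,
        },
        index=manifest.index,
    )


def _cell_line_column(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    truth: pd.DataFrame,
    kind: str,
) -> np.ndarray:
    """Beta values for parental / resistant / dko cell-line samples."""
    n = len(truth)
    low, high, _, mid = _component_draws(rng, cfg, n)
    shoulder_u = rng.random(n)  # drawn for every kind to keep rng order fixed
    parental_high = truth["parental_high"].to_numpy()
    retained = truth["retained"].to_numpy()
    col = low.copy()
    if kind == "parental":
        col[parental_high] = high[parental_high]
    elif kind in ("resistant", "dko"):
        col[retained] = high[retained]
        lost = parental_high & ~retained
        if kind == "resistant" and cfg.intermediate_shoulder_prob > 0:
            in_mid = lost & (shoulder_u < cfg.intermediate_shoulder_prob)
            col[in_mid] = mid[in_mid]
    else:  # pragma: no cover - internal
        raise ValueError(kind)
    return col


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a full synthetic dataset (manifest, betas, samples, truth).

    Deterministic given ``config.seed``. Sample groups: one parental, one
    resistant, one dko cell line, then normal tissues (males before
    females), tumors and adjacent normals (alternating female/male sexes).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    manifest = _build_manifest(rng, config)
    truth = _build_truth(rng, config, manifest)

    columns: dict[str, np.ndarray] = {}
    sheet_rows: list[tuple[str, str, str, str]] = []

    for sid, kind in (("parental_1", "parental"), ("resistant_1", "resistant"), ("dko_1", "dko")):
        columns[sid] = _cell_line_column(rng, config, truth, kind)
        sheet_rows.append((sid, kind, "male", "cell_line"))

    for i in range(config.n_normal_male):
        sid = f"normal_male_{i + 1}"
        columns[sid] = _normal_tissue_column(rng, config, truth, "male")
        sheet_rows.append((sid, "normal_tissue", "male", "mixed_panel"))
    for i in range(config.n_normal_female):
        sid = f"normal_female_{i + 1}"
        columns[sid] = _normal_tissue_column(rng, config, truth, "female")
        sheet_rows.append((sid, "normal_tissue", "female", "mixed_panel"))

    de_novo = (truth["cancer_state"] == "de_novo_methylated").to_numpy()
    for i in range(config.n_tumor):
        sex = "female" if i % 2 == 0 else "male"
        sid = f"tumor_{i + 1}"
        base = _normal_tissue_column(rng, config, truth, sex)
        hit = de_novo & (rng.random(len(truth)) < config.tumor_penetrance)
        high = rng.beta(*config.beta_shape_high, size=len(truth))
        base[hit] = high[hit]
        columns[sid] = base
        sheet_rows.append((sid, "tumor", sex, "colon"))
    for i in range(config.n_adjacent):
        sex = "female" if i % 2 == 0 else "male"
        sid = f"adjacent_{i + 1}"
        columns[sid] = _normal_tissue_column(rng, config, truth, sex)
        sheet_rows.append((sid, "adjacent_normal", sex, "colon"))

    betas = BetaMatrix(
        pd.DataFrame(columns, index=manifest.index), validate=False
    )
    samples = validate_sample_sheet(
        pd.DataFrame(sheet_rows, columns=["sample_id", "group", "sex", "tissue"])
    )
    return SimulatedDataset(manifest=manifest, betas=betas, samples=samples, truth=truth)


def simulate_cohort(
    config: SimulationConfig,
    manifest: pd.DataFrame,
    truth: pd.DataFrame,
    probe_set: Sequence[str],
    *,
    penetrance: float | None = None,
) -> tuple[BetaMatrix, pd.DataFrame]:
    """Generate a tumor / adjacent-normal cohort over a selected probe set.

    Tumors methylate each probe in *probe_set* independently with the given
    per-probe *penetrance* (default ``config.tumor_penetrance``); all other
    probes, and all adjacent normals, follow the sex-specific non-cancer
    pattern from *truth*. A separate rng stream (derived from the config
    seed) keeps the cohort independent of :func:`simulate_dataset` draws.
    """
    config.validate()
    probe_idx = pd.Index(probe_set)
    if probe_idx.empty:
        raise ConfigError("probe_set must not be empty")
    missing = probe_idx.difference(manifest.index)
    if len(missing):
        raise ConfigError(f"probe_set entries absent from manifest: {list(missing[:5])}")
    pen = config.tumor_penetrance if penetrance is None else float(penetrance)
    if not 0.0 <= pen <= 1.0:
        raise ConfigError(f"penetrance must be in [0,1], got {pen}")

    rng = np.random.default_rng([config.seed, 9157])
    selected = manifest.index.isin(probe_idx)
    columns: dict[str, np.ndarray] = {}
    sheet_rows = []
    for i in range(config.n_tumor):
        sex = "female" if i % 2 == 0 else "male"
        sid = f"cohort_tumor_{i + 1}"
        base = _normal_tissue_column(rng, config, truth, sex)
        hit = selected & (rng.random(len(truth)) < pen)
        high = rng.beta(*config.beta_shape_high, size=len(truth))
        base[hit] = high[hit]
        columns[sid] = base
        sheet_rows.append((sid, "tumor", sex, "colon"))
    for i in range(config.n_adjacent):
        sex = "female" if i % 2 == 0 else "male"
        sid = f"cohort_adjacent_{i + 1}"
        columns[sid] = _normal_tissue_column(rng, config, truth, sex)
        sheet_rows.append((sid, "adjacent_normal", sex, "colon"))

    if not columns:
        raise ConfigError("cohort has zero samples (n_tumor and n_adjacent both 0)")
    betas = BetaMatrix(pd.DataFrame(columns, index=manifest.index), validate=False)
    samples = validate_sample_sheet(
        pd.DataFrame(sheet_rows, columns=["sample_id", "group", "sex", "tissue"])
    )
    return betas, samples


def config_with(config: SimulationConfig, **overrides) -> SimulationConfig:
    """Return a copy of *config* with fields replaced (convenience wrapper)."""
    return replace(config, **overrides)
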