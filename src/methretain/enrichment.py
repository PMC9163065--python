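"""Chromosome enrichment-bias statistic with hypergeometric testing.

For each chromosome, bookkeeping over the population of parental-high
probes (probes with beta >= cutoff in the parental line, genome-wide):

    q = retained-high probes on the chromosome in the compromised line
    m = parental-high probes on the chromosome
    n = parental-high probes NOT on the chromosome
    k = retained-high probes genome-wide

The expected retained count under random allocation is ``e = (m/(m+n))*k``
and the percent enrichment bias is ``100*(q-e)/k``; positive values mean
more retention on the chromosome than chance, negative less. Significance
uses a direction-matched one-sided hypergeometric tail: upper
P(X >= q) for enrichment (q >= e), lower P(X <= q) for depletion.

Because q and e each sum to k over chromosomes, the percent biases sum to
zero analytically; this is asserted on every run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .arrays import BetaMatrix, chromosome_sort_key
from .errors import DegenerateInputError, ValidationError
from .retention import call_high, _align_chromosomes

DEFAULT_CUTOFF = 0.7
DEFAULT_ALPHA = 1e-6


def expected_retained(m: int, n: int, k: int) -> float:
    """Expected retained count on a chromosome by chance: (m/(m+n)) * k."""
    if m < 0 or n < 0 or k < 0:
        raise ValidationError(f"counts must be >= 0, got m={m}, n={n}, k={k}")
    if m + n == 0:
        raise DegenerateInputError("m + n = 0: empty parental-high population")
    return (m / (m + n)) * k


def percent_enrichment_bias(q: int, e: float, k: int) -> float:
    """Percent enrichment bias: 100 * (q - e) / k."""
    if k <= 0:
        raise DegenerateInputError("k must be > 0 for percent bias")
    return 100.0 * (q - e) / k


def hypergeom_tail(q: int, m: int, n: int, k: int) -> tuple[float, str]:
    """Direction-matched one-sided hypergeometric tail probability.

    X ~ Hypergeometric(population m+n, successes m, draws k). Returns
    (p, tail) with tail "upper" (P(X >= q), computed as sf(q-1)) when
    q >= e and "lower" (P(X <= q)) otherwise.
    """
    if q < 0 or m < 0 or n < 0 or k < 0:
        raise ValidationError(f"counts must be >= 0: q={q}, m={m}, n={n}, k={k}")
    if q > m:
        raise ValidationError(f"q={q} exceeds chromosome parental-high count m={m}")
    if q > k:
        raise ValidationError(f"q={q} exceeds genome-wide retained count k={k}")
    if k > m + n:
        raise ValidationError(f"k={k} exceeds population size m+n={m + n}")
    dist = hypergeom(M=m + n, n=m, N=k)
    e = expected_retained(m, n, k)
    if q >= e:
        return float(dist.sf(q - 1)), "upper"
    return float(dist.cdf(q)), "lower"


def enrichment_analysis(
    betas: BetaMatrix,
    manifest: pd.DataFrame,
    parental_id: str,
    compromised_id: str,
    cutoff: float = DEFAULT_CUTOFF,
    alpha: float = DEFAULT_ALPHA,
    *,
    include_chry: bool = False,
) -> pd.DataFrame:
    """Per-chromosome enrichment records for retained methylation.

    Returns a DataFrame with columns chromosome, q, m, n, k, e, pct_bias,
    p_value, tail, significant and a Bonferroni-adjusted ``p_bonferroni``
    extra column (the significance flag uses the raw p at *alpha*).
    chrY is excluded from the population by default.
    """
    chrom = _align_chromosomes(betas, manifest)
    parental_high = call_high(betas, parental_id, cutoff)
    retained = parental_high & call_high(betas, compromised_id, cutoff)
    if not include_chry:
        on_y = (chrom == "chrY").to_numpy()
        parental_high &= ~on_y
        retained &= ~on_y

    total_m = int(parental_high.sum())
    if total_m == 0:
        raise DegenerateInputError("no parental-high probes genome-wide")
    k = int(retained.sum())

    m_by = parental_high.groupby(chrom, observed=True).sum()
    q_by = retained.groupby(chrom, observed=True).sum()
    chroms = [
        c for c in sorted(chrom.unique(), key=chromosome_sort_key)
        if include_chry or c != "chrY"
    ]
    rows = []
    for c in chroms:
        m = int(m_by.get(c, 0))
        if m == 0:
            continue  # no parental-high probes: chromosome not in the draw
        q = int(q_by.get(c, 0))
        n = total_m - m
        e = expected_retained(m, n, k)
        bias = percent_enrichment_bias(q, e, k) if k > 0 else 0.0
        p, tail = hypergeom_tail(q, m, n, k)
        rows.append((c, q, m, n, k, e, bias, p, tail))
    records = pd.DataFrame(
        rows, columns=["chromosome", "q", "m", "n", "k", "e", "pct_bias", "p_value", "tail"]
    )
    records["p_bonferroni"] = np.minimum(records["p_value"] * len(records), 1.0)
    records["significant"] = records["p_value"] <= alpha

    # analytic invariants: sum q = sum e = k, so percent biases cancel
    assert int(records["q"].sum()) == k
    assert np.isclose(records["e"].sum(), k, rtol=1e-9)
    if k > 0:
        assert abs(records["pct_bias"].sum()) <= 1e-9 * 100.0
    return records
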