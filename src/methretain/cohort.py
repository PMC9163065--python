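"""Descriptive cross-cohort validation of classified probes.

Given a tumor / adjacent-normal beta matrix (450K-style or simulated) and
a probe set of interest, summarizes methylation per probe by sex and
tissue type and quantifies tumor hypermethylation. Because baseline chrX
methylation differs by sex (monoallelic ~0.5 in females, ~0 in males),
all deltas are sex-stratified and the default hypermethylation call is
relative to the sex-matched adjacent-normal mean.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .arrays import BetaMatrix
from .errors import ValidationError

#: Tumor "hypermethylated" call: beta at least this much above the
#: sex-matched adjacent-normal mean (relative mode) ...
DEFAULT_REL_DELTA = 0.3
#: ... or at least this absolute beta (absolute mode).
DEFAULT_ABS_CUTOFF = 0.7


def intersect_probe_sets(
    query_probes: Sequence[str], target_manifest: pd.DataFrame | pd.Index
) -> tuple[pd.Index, dict[str, int]]:
    """Probes present on both platforms, plus a count report.

    *target_manifest* may be a manifest DataFrame (indexed by probe id) or
    a bare probe-id Index, e.g. an HM450 manifest when the query set comes
    from EPIC. Query order is preserved.
    """
    query = pd.Index(query_probes)
    target = (
        target_manifest
        if isinstance(target_manifest, pd.Index)
        else target_manifest.index
    )
    if query.empty or target.empty:
        raise ValidationError("both probe sets must be nonempty")
    shared = query[query.isin(target)]
    report = {
        "n_query": int(len(query)),
        "n_target": int(len(target)),
        "n_shared": int(len(shared)),
    }
    return shared, report


def order_samples(samples: pd.DataFrame) -> list[str]:
    """Sample ids ordered sex-major, then tissue type (tumor before normal).

    This is the column layout contract for cohort heatmaps: females first,
    within each sex tumors before adjacent normals, stable within groups.
    """
    sex_rank = {"female": 0, "male": 1}
    group_rank = {"tumor": 0, "adjacent_normal": 1}
    keyed = samples.assign(
        _sex=samples["sex"].map(sex_rank), _grp=samples["group"].map(group_rank)
    )
    keyed = keyed.dropna(subset=["_sex", "_grp"])
    return list(keyed.sort_values(["_sex", "_grp"], kind="mergesort").index)


def cohort_summary(
    betas: BetaMatrix,
    samples: pd.DataFrame,
    probe_set: Sequence[str],
    *,
    hyper_mode: str = "relative",
    rel_delta: float = DEFAULT_REL_DELTA,
    abs_cutoff: float = DEFAULT_ABS_CUTOFF,
) -> pd.DataFrame:
    """Per-probe cohort summary over tumor and adjacent-normal samples.

    For every probe in *probe_set*: mean beta and sample count per
    (sex x tissue-type) cell, the per-sex tumor-minus-adjacent delta, and
    ``tumor_hyper_fraction`` — the fraction of tumor samples called
    hypermethylated. The call is either *relative* (beta >= sex-matched
    adjacent-normal mean + rel_delta) or *absolute* (beta >= abs_cutoff).
    Cells with zero samples are NaN; rows are sorted by
    tumor_hyper_fraction descending (ties by probe id).
    """
    if hyper_mode not in ("relative", "absolute"):
        raise ValidationError(f"unknown hyper_mode {hyper_mode!r}")
    probes = pd.Index(probe_set)
    if probes.empty:
        raise ValidationError("probe_set must not be empty")
    sub = betas.subset_probes(probes).values

    cohort = samples[samples["group"].isin(["tumor", "adjacent_normal"])]
    cells: dict[str, pd.Series] = {}
    ns: dict[str, int] = {}
    for sex in ("female", "male"):
        for group in ("tumor", "adjacent_normal"):
            ids = cohort.index[(cohort["sex"] == sex) & (cohort["group"] == group)]
            ids = ids.intersection(sub.columns)
            key = f"{sex}_{group}"
            ns[f"n_{key}"] = len(ids)
            if len(ids):
                cells[f"mean_{key}"] = sub[list(ids)].mean(axis=1, skipna=True)
            else:
                cells[f"mean_{key}"] = pd.Series(np.nan, index=sub.index)

    out = pd.DataFrame(cells, index=sub.index)
    for key, n in ns.items():
        out[key] = n
    for sex in ("female", "male"):
        out[f"delta_mean_{sex}"] = (
            out[f"mean_{sex}_tumor"] - out[f"mean_{sex}_adjacent_normal"]
        )

    tumor_ids = cohort.index[cohort["group"] == "tumor"].intersection(sub.columns)
    if len(tumor_ids):
        tumor_vals = sub[list(tumor_ids)]
        if hyper_mode == "absolute":
            hyper = tumor_vals >= abs_cutoff
        else:
            cols = {}
            for sid in tumor_ids:
                sex = cohort.loc[sid, "sex"]
                baseline = out[f"mean_{sex}_adjacent_normal"]
                cols[sid] = tumor_vals[sid] >= (baseline + rel_delta)
            hyper = pd.DataFrame(cols)
        out["tumor_hyper_fraction"] = hyper.mean(axis=1)
    else:
        out["tumor_hyper_fraction"] = np.nan

    return out.sort_values(
        ["tumor_hyper_fraction"], ascending=False, kind="mergesort"
    )
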