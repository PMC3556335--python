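"""Expression quantification, NB differential expression, profile clusters.

Counts from the three berry stages (PFS: post fruit-set, PR: pre-ripening,
PHWII: second month of post-harvest withering; three biological replicates
each) are normalized by median-of-ratios size factors, tested for
differential expression between adjacent stages with an exact-style
conditional negative-binomial test (pooled method-of-moments dispersion),
and significant genes (FDR <= 0.05, |log2 fold change| >= 1) are assigned
to one of four development profiles: 1 repressed, 2 transiently repressed,
3 transiently induced, 4 induced.  Gene groups are tested for term
enrichment with the hypergeometric upper tail and Benjamini-Hochberg
control.

The NB pipeline is a deliberately transparent re-implementation of the
classic count-based testing scheme; numerical parity with any specific
package is not claimed — calibration is established by simulation in the
test suite instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .formats_io import CountTable

STAGES = ("PFS", "PR", "PHWII")

PROFILE_NAMES = {
    1: "repressed",
    2: "transiently_repressed",
    3: "transiently_induced",
    4: "induced",
}


@dataclass
class ExpressionRecord:
    feature_id: str
    sample_id: str
    count: int
    fpkm: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (0 <= self.ci_low <= self.fpkm <= self.ci_high):
            raise ValueError(
                f"{self.feature_id}/{self.sample_id}: CI must bracket FPKM"
            )


@dataclass
class DEResult:
    feature_id: str
    contrast: tuple[str, str]
    log2_fc: float
    moderated_log2_fc: float
    p_value: float
    p_adjusted: float


@dataclass
class EnrichmentResult:
    term_id: str
    group: str
    overlap: int
    group_size: int
    term_size: int
    universe_size: int
    p_value: float
    p_adjusted: float


# ---------------------------------------------------------------------------
# FPKM and the expressed-gene rule
# ---------------------------------------------------------------------------


def compute_fpkm(
    table: CountTable, lengths: dict[str, int]
) -> list[ExpressionRecord]:
    """Fragments per kilobase of exon model per million mapped fragments.

    The 95% CI comes from a normal approximation on the count
    (count +- 1.96*sqrt(count), floored at 0; an upper bound of 3.84 for a
    zero count) rescaled to FPKM units.
    """
    totals = table.counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero total mapped fragments in samples {bad}")
    records = []
    for fid in table.counts.index:
        length_kb = lengths[fid] / 1000.0
        if length_kb <= 0:
            raise ValueError(f"non-positive exon-model length for {fid}")
        for sid in table.counts.columns:
            count = int(table.counts.at[fid, sid])
            scale = 1.0 / (length_kb * totals[sid] / 1e6)
            half = 1.96 * math.sqrt(count)
            hi_count = count + half if count > 0 else 3.84
            records.append(
                ExpressionRecord(
                    feature_id=str(fid),
                    sample_id=str(sid),
                    count=count,
                    fpkm=count * scale,
                    ci_low=max(0.0, count - half) * scale,
                    ci_high=hi_count * scale,
                )
            )
    return records


def is_expressed(record: ExpressionRecord, min_fpkm: float = 0.001) -> bool:
    """Expressed iff the FPKM 95% CI lower bound exceeds zero and the FPKM
    itself exceeds ``min_fpkm`` (both strictly)."""
    return record.ci_low > 0.0 and record.fpkm > min_fpkm


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def size_factors(
    counts: pd.DataFrame, pseudo_reference: bool = False
) -> dict[str, float]:
    """Median-of-ratios size factors.

    Each sample's factor is the median, over features nonzero in every
    sample, of its count divided by the feature's geometric mean.  With no
    such feature the default is to fail; ``pseudo_reference=True`` falls
    back to a geometric mean over the positive counts only.
    """
    arr = counts.to_numpy(dtype=float)
    all_nonzero = (arr > 0).all(axis=1)
    if not all_nonzero.any():
        if not pseudo_reference:
            raise ValueError(
                "no feature with nonzero counts in all samples; "
                "retry with pseudo_reference=True"
            )
        some = (arr > 0).any(axis=1)
        sub = arr[some]
        with np.errstate(divide="ignore"):
            logs = np.where(sub > 0, np.log(np.where(sub > 0, sub, 1.0)), np.nan)
        ref = np.exp(np.nanmean(logs, axis=1))
    else:
        sub = arr[all_nonzero]
        ref = np.exp(np.log(sub).mean(axis=1))
    factors = {}
    for j, sample in enumerate(counts.columns):
        ratios = sub[:, j] / ref
        ratios = ratios[np.isfinite(ratios) & (ratios > 0)]
        if ratios.size == 0:
            raise ValueError(f"cannot estimate size factor for sample {sample}")
        factors[str(sample)] = float(np.median(ratios))
    return factors


# ---------------------------------------------------------------------------
# NB differential expression
# ---------------------------------------------------------------------------


def _condition_dispersion(norm: np.ndarray, inv_s_mean: float) -> float:
    """Method-of-moments NB dispersion from one condition's normalized
    counts (Var(K/s) = mu*E[1/s] + alpha*mu^2)."""
    m = norm.mean()
    if m <= 0 or norm.size < 2:
        return 0.0
    v = norm.var(ddof=1)
    return (v - m * inv_s_mean) / (m * m)


def _nb_params(mean: float, var: float) -> tuple[float, float]:
    """scipy (n, p) for a negative binomial with the given mean/variance;
    degenerates to near-Poisson when var <= mean."""
    var = max(var, mean * (1 + 1e-8))
    p = mean / var
    n = mean * mean / (var - mean)
    return n, p


def nb_test(
    table: CountTable,
    stage_a: str,
    stage_b: str,
    dispersion_floor: float = 1e-8,
    moderated_pseudocount: float = 8.0,
) -> list[DEResult]:
    """Exact-style conditional NB test of equal means between two stages.

    Per feature, the replicate sums in each stage are modelled as negative
    binomials sharing the pooled mean; conditional on the observed total,
    the two-sided p-value sums the probabilities of all splits at most as
    likely as the observed one.  Dispersion is a per-feature
    method-of-moments estimate, the maximum over the two conditions,
    floored at ``dispersion_floor``.  BH adjustment runs across features
    within the contrast; all-zero features get p = 1 and are excluded from
    the BH denominator.
    """
    samples_a = table.samples_of(stage_a)
    samples_b = table.samples_of(stage_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("need >= 2 replicates per stage")
    factors = size_factors(table.counts, pseudo_reference=True)
    s_a = np.array([factors[s] for s in samples_a])
    s_b = np.array([factors[s] for s in samples_b])
    counts_a = table.counts[samples_a].to_numpy(dtype=float)
    counts_b = table.counts[samples_b].to_numpy(dtype=float)

    mod = moderated_lfc(
        table, stage_a, stage_b, pseudocount=moderated_pseudocount,
        factors=factors
    )

    results = []
    p_values = []
    testable = []
    for i, fid in enumerate(table.counts.index):
        ka_reps, kb_reps = counts_a[i], counts_b[i]
        k_a, k_b = ka_reps.sum(), kb_reps.sum()
        total = k_a + k_b
        norm_a, norm_b = ka_reps / s_a, kb_reps / s_b
        lfc = math.log2((norm_b.mean() + 1.0) / (norm_a.mean() + 1.0))
        if total == 0:
            results.append(
                DEResult(str(fid), (stage_a, stage_b), lfc, mod[str(fid)], 1.0, 1.0)
            )
            continue
        # MoM dispersion from few replicates is biased low; take the max
        # over conditions and apply an n/(n-1) small-sample correction
        n_min = min(len(norm_a), len(norm_b))
        alpha = max(
            _condition_dispersion(norm_a, float(np.mean(1.0 / s_a))),
            _condition_dispersion(norm_b, float(np.mean(1.0 / s_b))),
        ) * (n_min / (n_min - 1))
        alpha = max(alpha, dispersion_floor)
        q = total / (s_a.sum() + s_b.sum())
        mu_a, mu_b = q * s_a.sum(), q * s_b.sum()
        var_a = mu_a + alpha * q * q * float((s_a * s_a).sum())
        var_b = mu_b + alpha * q * q * float((s_b * s_b).sum())
        n_a, p_a = _nb_params(mu_a, var_a)
        n_b, p_b = _nb_params(mu_b, var_b)
        grid = np.arange(0, int(total) + 1)
        log_f = stats.nbinom.logpmf(grid, n_a, p_a) + stats.nbinom.logpmf(
            grid[::-1], n_b, p_b
        )
        f = np.exp(log_f - log_f.max())
        f_obs = f[int(k_a)]
        p = float(f[f <= f_obs * (1 + 1e-10)].sum() / f.sum())
        p = min(1.0, p)
        results.append(
            DEResult(str(fid), (stage_a, stage_b), lfc, mod[str(fid)], p, 1.0)
        )
        p_values.append(p)
        testable.append(len(results) - 1)
    if p_values:
        _rej, adj, _a, _b = multipletests(p_values, method="fdr_bh")
        for idx, padj in zip(testable, adj):
            results[idx].p_adjusted = float(max(padj, results[idx].p_value))
    return results


def moderated_lfc(
    table: CountTable,
    stage_a: str,
    stage_b: str,
    pseudocount: float = 8.0,
    factors: dict[str, float] | None = None,
) -> dict[str, float]:
    """Shifted-log moderated fold change: difference of mean
    log2(normalized count + pseudocount) between stages.  The shift damps
    fold changes for low counts and converges to the raw log-ratio as
    counts grow."""
    if factors is None:
        factors = size_factors(table.counts, pseudo_reference=True)
    samples_a = table.samples_of(stage_a)
    samples_b = table.samples_of(stage_b)
    out = {}
    for fid in table.counts.index:
        row = table.counts.loc[fid]
        la = np.mean(
            [math.log2(row[s] / factors[s] + pseudocount) for s in samples_a]
        )
        lb = np.mean(
            [math.log2(row[s] / factors[s] + pseudocount) for s in samples_b]
        )
        out[str(fid)] = float(lb - la)
    return out


# ---------------------------------------------------------------------------
# profile clustering
# ---------------------------------------------------------------------------


def _signed_significance(res: DEResult, fdr: float, min_lfc: float) -> int:
    if res.p_adjusted <= fdr and abs(res.log2_fc) >= min_lfc:
        return 1 if res.log2_fc > 0 else -1
    return 0


#: (sign PFS->PR, sign PR->PHWII) -> cluster
_PATTERN = {
    (-1, -1): 1, (-1, 0): 1, (0, -1): 1,
    (-1, 1): 2,
    (1, -1): 3,
    (1, 1): 4, (1, 0): 4, (0, 1): 4,
}


def assign_profile_cluster(
    de_first: list[DEResult],
    de_second: list[DEResult],
    fdr: float = 0.05,
    min_lfc: float = 1.0,
) -> dict[str, int | None]:
    """Four-pattern development profile from the two adjacent-stage tests.

    Cluster 1 (repressed): down in both steps or down in exactly one;
    2 (transiently repressed): down then up; 3 (transiently induced): up
    then down; 4 (induced): up in both or in exactly one.  Features
    significant in neither contrast get no cluster.
    """
    first = {r.feature_id: r for r in de_first}
    second = {r.feature_id: r for r in de_second}
    out: dict[str, int | None] = {}
    for fid in first:
        d1 = _signed_significance(first[fid], fdr, min_lfc)
        d2 = _signed_significance(second[fid], fdr, min_lfc) if fid in second else 0
        out[fid] = _PATTERN.get((d1, d2))
    return out


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


def enrich_terms(
    groups: dict[str, set[str]],
    term_map: dict[str, set[str]],
    universe: set[str],
    fdr: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric upper-tail enrichment of each term in each group,
    BH-adjusted across terms within the group.  Terms with no universe
    members are skipped; a result is enriched when p_adjusted < ``fdr``
    (threshold left to the caller, stored values are the statistics)."""
    term_members: dict[str, set[str]] = {}
    for gene, terms in term_map.items():
        if gene in universe:
            for t in terms:
                term_members.setdefault(t, set()).add(gene)
    n_universe = len(universe)
    results: list[EnrichmentResult] = []
    for group_name in sorted(groups):
        members = groups[group_name] & universe
        rows = []
        for term in sorted(term_members):
            in_term = term_members[term]
            k = len(members & in_term)
            p = float(
                stats.hypergeom.sf(k - 1, n_universe, len(in_term), len(members))
            )
            rows.append((term, k, len(in_term), min(1.0, p)))
        if not rows:
            continue
        _rej, adj, _a, _b = multipletests([r[3] for r in rows], method="fdr_bh")
        for (term, k, term_size, p), padj in zip(rows, adj):
            results.append(
                EnrichmentResult(
                    term_id=term,
                    group=group_name,
                    overlap=k,
                    group_size=len(members),
                    term_size=term_size,
                    universe_size=n_universe,
                    p_value=p,
                    p_adjusted=float(max(padj, p)),
                )
            )
    return results
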