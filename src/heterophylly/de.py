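"""Differential-expression testing for gene-level count matrices.

Implements the desk-scale RNA-seq DE stack used throughout the pipeline:
within-sample TPM normalization and low-expression filtering, trimmed-mean
(TMM) between-sample normalization, a method-of-moments common negative-
binomial dispersion, the conditional exact two-group NB test, and
Benjamini-Hochberg FDR control with signed DEG calls.

The negative binomial is parameterized by mean ``mu`` and dispersion ``phi``
with variance ``mu + phi * mu**2`` (``phi = 0`` is the Poisson limit).  Under
a shared dispersion the group-A total conditioned on the grand total follows
a beta-binomial law, which the exact test enumerates directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "compute_tpm",
    "filter_low_expression",
    "tmm_factors",
    "estimate_common_dispersion",
    "exact_nb_test",
    "bh_adjust",
    "call_degs",
    "run_comparison",
]

REQUIRED_METADATA_COLUMNS = ("sample_id", "species", "condition", "stage", "replicate")


@dataclass
class CountMatrix:
    """Gene x sample integer counts with effective lengths and sample metadata.

    Parameters
    ----------
    counts : DataFrame
        Genes in rows (index = gene identifiers), samples in columns.
    lengths : Series
        Per-gene effective length in bases, indexed like ``counts``.
    metadata : DataFrame
        One row per sample with columns ``sample_id, species, condition,
        stage, replicate``; must cover every column of ``counts``.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    metadata: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            dup = counts.index[counts.index.duplicated()][0]
            raise ValueError(f"duplicate gene identifier: {dup!r}")
        arr = counts.to_numpy()
        if arr.size and (arr < 0).any():
            raise ValueError("counts must be non-negative")
        self.lengths = self.lengths.reindex(counts.index)
        if self.lengths.isna().any():
            missing = self.lengths.index[self.lengths.isna()][0]
            raise ValueError(f"missing effective length for gene {missing!r}")
        if (self.lengths <= 0).any():
            raise ValueError("effective lengths must be positive")
        if self.metadata is not None:
            meta = self.metadata
            for col in REQUIRED_METADATA_COLUMNS:
                if col not in meta.columns:
                    raise ValueError(f"metadata lacks required column {col!r}")
            known = set(meta["sample_id"])
            unknown = [s for s in counts.columns if s not in known]
            if unknown:
                raise ValueError(f"samples missing from metadata: {unknown}")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def subset_samples(self, sample_ids) -> "CountMatrix":
        meta = None
        if self.metadata is not None:
            meta = self.metadata[self.metadata["sample_id"].isin(sample_ids)].copy()
        return CountMatrix(self.counts[list(sample_ids)], self.lengths, meta)

    def subset_genes(self, gene_ids) -> "CountMatrix":
        meta = None if self.metadata is None else self.metadata.copy()
        return CountMatrix(self.counts.loc[list(gene_ids)], self.lengths.loc[list(gene_ids)], meta)


def compute_tpm(counts: CountMatrix) -> pd.DataFrame:
    """Transcripts-per-million per (gene, sample).

    TPM = 1e6 * (count / length) / sum_genes(count / length), so every
    sample column sums to 1e6.  A sample with zero counts everywhere has no
    defined TPM and raises.
    """
    rate = counts.counts.div(counts.lengths, axis=0)
    denom = rate.sum(axis=0)
    dead = denom.index[denom == 0]
    if len(dead):
        raise ValueError(f"sample {dead[0]!r} has no reads; TPM undefined")
    return rate.div(denom, axis=1) * 1e6


def filter_low_expression(tpm: pd.DataFrame, threshold: float = 1.0) -> pd.Index:
    """Genes reaching ``TPM >= threshold`` in at least one sample.

    The complement — genes below the floor in *every* sample — is dropped
    from all downstream analyses.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if tpm.empty:
        return tpm.index
    return tpm.index[(tpm >= threshold).any(axis=1)]


def _choose_reference(counts: pd.DataFrame, lib_sizes: pd.Series) -> str:
    # sample whose upper-quartile (of depth-scaled counts) is closest to the mean
    scaled = counts.div(lib_sizes, axis=1)
    uq = scaled.quantile(0.75, axis=0)
    return (uq - uq.mean()).abs().idxmin()


def tmm_factors(
    counts: CountMatrix | pd.DataFrame,
    reference_sample: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, one per sample.

    Log-ratios (M) and log-intensities (A) against the reference sample are
    computed on genes expressed in both samples; the extreme ``trim_m``
    (resp. ``trim_a``) fraction of each tail of M (resp. A) is discarded and
    the remaining M values are averaged with inverse-variance weights.  The
    returned factors are rescaled to geometric mean 1; multiplying library
    sizes by them gives effective library sizes.
    """
    table = counts.counts if isinstance(counts, CountMatrix) else counts
    if table.shape[1] < 2:
        raise ValueError("TMM requires at least two samples")
    lib = table.sum(axis=0).astype(float)
    if (lib == 0).any():
        raise ValueError("zero-depth sample")
    ref = reference_sample if reference_sample is not None else _choose_reference(table, lib)
    if ref not in table.columns:
        raise ValueError(f"unknown reference sample {ref!r}")

    y_r = table[ref].to_numpy(dtype=float)
    n_r = lib[ref]
    factors = {}
    for sample in table.columns:
        if sample == ref:
            factors[sample] = 1.0
            continue
        y_s = table[sample].to_numpy(dtype=float)
        n_s = lib[sample]
        both = (y_s > 0) & (y_r > 0)
        if not both.any():
            raise ValueError(f"sample {sample!r} shares no expressed genes with reference {ref!r}")
        ps, pr = y_s[both] / n_s, y_r[both] / n_r
        m = np.log2(ps / pr)
        a = 0.5 * np.log2(ps * pr)
        w = (n_s - y_s[both]) / (n_s * y_s[both]) + (n_r - y_r[both]) / (n_r * y_r[both])

        n = m.size
        rank_m = stats.rankdata(m, method="ordinal")
        rank_a = stats.rankdata(a, method="ordinal")
        keep = (
            (rank_m > n * trim_m)
            & (rank_m <= n * (1.0 - trim_m))
            & (rank_a > n * trim_a)
            & (rank_a <= n * (1.0 - trim_a))
        )
        if not keep.any():
            keep = np.ones(n, dtype=bool)  # degenerate tiny input: fall back untrimmed
        factors[sample] = float(2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep])))

    out = pd.Series(factors).reindex(table.columns)
    out /= np.exp(np.log(out).mean())  # geometric mean 1
    out.name = "tmm_factor"
    return out


def effective_library_sizes(counts: CountMatrix | pd.DataFrame, factors: pd.Series) -> pd.Series:
    table = counts.counts if isinstance(counts, CountMatrix) else counts
    return table.sum(axis=0).astype(float) * factors.reindex(table.columns)


def normalized_counts(counts: CountMatrix | pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Counts rescaled to the geometric-mean effective library size."""
    table = counts.counts if isinstance(counts, CountMatrix) else counts
    eff = effective_library_sizes(table, factors)
    target = float(np.exp(np.log(eff).mean()))
    return table.mul(target / eff, axis=1)


def estimate_common_dispersion(
    counts: CountMatrix | pd.DataFrame,
    groups: pd.Series | dict,
    factors: pd.Series | None = None,
) -> float:
    """Single common NB dispersion phi by method of moments.

    Per gene, within-group sample means and variances on normalized counts
    give ``phi_g = (v - m) / m**2`` (pooled over groups with >= 2
    replicates); the common phi is the median over genes with positive
    pooled mean, floored at 0.
    """
    table = counts.counts if isinstance(counts, CountMatrix) else counts
    groups = pd.Series(groups).reindex(table.columns)
    if factors is None:
        factors = pd.Series(1.0, index=table.columns)
    norm = normalized_counts(table, factors)

    replicated = [g for g, members in groups.groupby(groups) if len(members) >= 2]
    if not replicated:
        raise ValueError("dispersion estimation needs at least one group with replicates")

    num = np.zeros(len(table.index))
    dof = 0.0
    means = []
    weights = []
    for g in replicated:
        cols = groups.index[groups == g]
        block = norm[cols].to_numpy()
        k = block.shape[1]
        means.append(block.mean(axis=1))
        weights.append(k)
        num += (k - 1) * block.var(axis=1, ddof=1)
        dof += k - 1
    pooled_var = num / dof
    pooled_mean = np.average(np.column_stack(means), axis=1, weights=weights)

    ok = pooled_mean > 0
    if not ok.any():
        return 0.0
    phi_g = (pooled_var[ok] - pooled_mean[ok]) / pooled_mean[ok] ** 2
    return float(max(0.0, np.median(phi_g)))


def _conditional_log_pmf(s: int, r_a: float, r_b: float) -> np.ndarray:
    """log P(Y_A = y | Y_A + Y_B = s) for y = 0..s under equal NB means.

    The conditional law is BetaBinomial(s, r_a, r_b) with r_g = n_g / phi;
    independent of the common mean and the NB success probability.
    """
    y = np.arange(s + 1, dtype=float)
    log_binom = gammaln(s + 1) - gammaln(y + 1) - gammaln(s - y + 1)
    log_kernel = gammaln(y + r_a) + gammaln(s - y + r_b)
    lp = log_binom + log_kernel
    return lp - logsumexp(lp)


def exact_nb_test(
    group_a,
    group_b,
    factors_a=None,
    factors_b=None,
    dispersion: float = 0.0,
    enumeration_cap: int = 5000,
) -> float:
    """Two-sided conditional exact NB test of equal means between two groups.

    Counts in each group are scaled to a common effective depth (via the
    supplied per-sample factors), summed, and the group-A total is tested
    against its conditional distribution given the grand total.  The
    two-sided p-value sums the probabilities of all outcomes no more likely
    than the observed one.  At ``dispersion == 0`` the conditional law is
    binomial (the Poisson/binomial exact test); above ``enumeration_cap``
    grand total, a normal approximation with continuity correction is used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    if factors_a is not None:
        a = a / np.asarray(factors_a, dtype=float)
    if factors_b is not None:
        b = b / np.asarray(factors_b, dtype=float)

    y_a = int(round(a.sum()))
    y_b = int(round(b.sum()))
    s = y_a + y_b
    if s == 0:
        warnings.warn("grand total 0: p-value 1 by convention", stacklevel=2)
        return 1.0

    n_a, n_b = a.size, b.size
    if dispersion == 0.0:
        p = n_a / (n_a + n_b)
        if s <= enumeration_cap:
            lp = stats.binom.logpmf(np.arange(s + 1), s, p)
            lp -= logsumexp(lp)
            return _two_sided_from_log_pmf(lp, y_a)
        mean, var = s * p, s * p * (1 - p)
    else:
        r_a, r_b = n_a / dispersion, n_b / dispersion
        if s <= enumeration_cap:
            lp = _conditional_log_pmf(s, r_a, r_b)
            return _two_sided_from_log_pmf(lp, y_a)
        r = r_a + r_b
        mean = s * r_a / r
        var = s * (r_a * r_b / r**2) * (r + s) / (r + 1.0)

    # normal approximation branch: doubled smaller tail, continuity corrected
    z_lo = (y_a + 0.5 - mean) / np.sqrt(var)
    z_hi = (y_a - 0.5 - mean) / np.sqrt(var)
    p_lo = stats.norm.cdf(z_lo)
    p_hi = stats.norm.sf(z_hi)
    return float(min(1.0, 2.0 * min(p_lo, p_hi)))


def _two_sided_from_log_pmf(lp: np.ndarray, observed: int) -> float:
    obs = lp[observed]
    # tolerance guards ties against round-off in log space
    mask = lp <= obs + 1e-12
    return float(min(1.0, np.exp(logsumexp(lp[mask]))))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (order preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    results: pd.DataFrame,
    fdr_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Attach signed DEG calls to a table with ``log2fc`` and ``qvalue``.

    A gene is called ``up``/``down`` by the sign of its fold-change when
    ``qvalue < fdr_threshold`` and ``|log2fc| > lfc_threshold`` (both strict,
    as the decision rule is stated); otherwise ``none``.
    """
    if fdr_threshold <= 0 or lfc_threshold <= 0:
        raise ValueError("thresholds must be positive")
    out = results.copy()
    sig = (out["qvalue"] < fdr_threshold) & (out["log2fc"].abs() > lfc_threshold)
    call = np.where(~sig, "none", np.where(out["log2fc"] > 0, "up", "down"))
    out["call"] = call
    return out


def run_comparison(
    counts: CountMatrix,
    treatment: str,
    reference: str,
    comparison_label: str | None = None,
    stage: str = "primordium",
    species: str | None = None,
    dispersion: float | None = None,
    fdr_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
    enumeration_cap: int = 5000,
) -> pd.DataFrame:
    """Full two-condition DEG table: TMM -> dispersion -> exact test -> BH -> calls.

    ``treatment`` and ``reference`` name condition labels in the metadata;
    log2 fold-changes are ``log2(treatment / reference)`` on normalized group
    means with a pseudo-count of 0.5 per group mean, so a positive call means
    higher expression under the treatment (e.g. aerial) than under the
    submerged-control reference.
    """
    meta = counts.metadata
    if meta is None:
        raise ValueError("comparison requires sample metadata")
    sel = meta["stage"] == stage
    if species is not None:
        sel &= meta["species"] == species
    t_samples = meta.loc[sel & (meta["condition"] == treatment), "sample_id"].tolist()
    r_samples = meta.loc[sel & (meta["condition"] == reference), "sample_id"].tolist()
    if not t_samples or not r_samples:
        raise ValueError(f"no samples for comparison {treatment!r} vs {reference!r} at stage {stage!r}")

    sub = counts.subset_samples(t_samples + r_samples)
    factors = tmm_factors(sub)
    groups = pd.Series(
        ["treatment"] * len(t_samples) + ["reference"] * len(r_samples),
        index=t_samples + r_samples,
    )
    if dispersion is None:
        dispersion = estimate_common_dispersion(sub, groups, factors)

    norm = normalized_counts(sub, factors)
    mean_t = norm[t_samples].mean(axis=1)
    mean_r = norm[r_samples].mean(axis=1)
    log2fc = np.log2((mean_t + 0.5) / (mean_r + 0.5))

    eff = effective_library_sizes(sub, factors)
    target = float(np.exp(np.log(eff).mean()))
    rel_t = (eff[t_samples] / target).to_numpy()
    rel_r = (eff[r_samples] / target).to_numpy()
    raw_t = sub.counts[t_samples].to_numpy()
    raw_r = sub.counts[r_samples].to_numpy()

    pvals = np.empty(len(sub.genes))
    for i in range(len(sub.genes)):
        pvals[i] = exact_nb_test(
            raw_t[i], raw_r[i], rel_t, rel_r,
            dispersion=dispersion, enumeration_cap=enumeration_cap,
        )

    label = comparison_label or f"{treatment}_vs_{reference}"
    table = pd.DataFrame(
        {
            "gene_id": sub.genes,
            "comparison": label,
            "log2fc": log2fc.to_numpy(),
            "pvalue": pvals,
            "qvalue": bh_adjust(pvals),
        }
    ).set_index("gene_id", drop=False)
    table.index.name = None
    return call_degs(table, fdr_threshold, lfc_threshold)
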