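"""Differential analysis of log2 intensity/count matrices.

The chain is the standard label-based proteomics workflow: per-sample median
normalization, left-censored ("downshifted normal") imputation of absent
values, a moderated two-sample t-statistic with empirical-Bayes variance
shrinkage, and a permutation-based FDR obtained by reshuffling genotype
labels within the tested growth phase.  Calling uses a fold-change threshold
plus an FDR threshold; DE features can then be clustered with k-means on
row-standardized profiles.

Variance shrinkage follows the classical hierarchical model: per-feature
residual variances s_i^2 with d degrees of freedom are assumed to follow a
scaled F distribution around a prior variance s0^2 with d0 prior degrees of
freedom; (d0, s0^2) are estimated by the method of moments on log s_i^2, and
the posterior variance is the precision-weighted blend
(d0*s0^2 + d*s_i^2)/(d0 + d).  With d0 = 0 the statistic reduces exactly to
the ordinary equal-variance two-sample t-test.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io_tables import FeatureMatrix

CALL_REDUCED = "reduced"
CALL_ENHANCED = "enhanced"
CALL_UNCHANGED = "unchanged"


@dataclass(frozen=True)
class Contrast:
    """A genotype comparison within one growth phase.

    log2 fold changes are signed as ``mean(test) - mean(reference)``, i.e.
    log2(mutant/WT) for the default orientation.
    """

    genotype_test: str = "mck1del"
    genotype_ref: str = "WT"
    phase: str = "PDS"


# ---------------------------------------------------------------------------
# Normalization and imputation
# ---------------------------------------------------------------------------

def median_normalize(matrix: FeatureMatrix) -> FeatureMatrix:
    """Shift each sample so per-sample medians of present values agree.

    The common target is the median of the per-sample medians, which makes
    the operation exactly idempotent.  Absent values stay absent.
    """
    values = matrix.values
    medians = values.median(axis=0, skipna=True)
    if medians.isna().any():
        bad = list(medians.index[medians.isna()])
        raise ValueError(f"samples with no present values: {bad}")
    target = float(np.median(medians.to_numpy()))
    out = values.add(target - medians, axis=1)
    return FeatureMatrix(out, matrix.layer, matrix.sample_metadata.copy())


def impute_missing(
    matrix: FeatureMatrix,
    width_factor: float = 0.3,
    downshift: float = 1.8,
    seed: int = 0,
) -> FeatureMatrix:
    """Replace absent values by draws from a downshifted normal.

    For each sample s with observed mean m_s and s.d. sd_s, absences are
    drawn from Normal(m_s - downshift*sd_s, (width_factor*sd_s)^2) — the
    usual left-censoring assumption for label-based proteomics, where
    missingness concentrates at the low-abundance end.
    """
    rng = np.random.default_rng(seed)
    values = matrix.values.copy()
    for sample in values.columns:
        col = values[sample]
        present = col.dropna()
        if col.isna().any() and len(present) < 3:
            raise ValueError(
                f"sample {sample!r} has {len(present)} present values; "
                "cannot estimate an imputation distribution"
            )
        n_missing = int(col.isna().sum())
        if n_missing == 0:
            continue
        m, sd = float(present.mean()), float(present.std(ddof=1))
        draws = rng.normal(m - downshift * sd, width_factor * sd, size=n_missing)
        values.loc[col.isna(), sample] = draws
    return FeatureMatrix(values, matrix.layer, matrix.sample_metadata.copy())


# ---------------------------------------------------------------------------
# Moderated test
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def estimate_prior(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) on log residual variances.

    Under s_i^2 ~ s0^2 * F(d, d0), log s_i^2 has a known mean/variance in
    terms of digamma/trigamma functions; matching the empirical moments of
    log s_i^2 yields the prior.  Returns ``(inf, s0sq)`` when the observed
    spread of variances is no larger than sampling noise alone.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = np.clip(s2, 1e-300, None)
    z = np.log(s2)
    e = z - special.polygamma(0, d / 2.0) + math.log(d / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) if len(e) > 1 else 0.0
    excess = e_var - float(special.polygamma(1, d / 2.0))
    if excess <= 0:
        # no excess spread beyond sampling noise: infinite prior df; the
        # raw-scale moment keeps posterior == s^2 when all variances agree
        return math.inf, float(np.mean(s2))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0sq = math.exp(
        e_mean + float(special.polygamma(0, d0 / 2.0)) - math.log(d0 / 2.0)
    )
    return d0, s0sq


def _moderated_stats(
    x1: np.ndarray, x2: np.ndarray, d0: float | None
) -> tuple[np.ndarray, np.ndarray, float, float, float]:
    """Core computation on two (features x replicates) blocks.

    Returns (log2FC, t, d0_used, s0sq_used, df_total).
    """
    n1, n2 = x1.shape[1], x2.shape[1]
    d = n1 + n2 - 2
    if d < 1:
        raise ValueError("zero residual degrees of freedom")
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    lfc = m1 - m2
    ss = x1.var(axis=1, ddof=1) * (n1 - 1) + x2.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / d
    if d0 is None:
        d0_used, s0sq = estimate_prior(s2, d)
    else:
        d0_used = float(d0)
        s0sq = float(np.median(s2)) if d0_used > 0 else 0.0
        if math.isinf(d0_used):
            pass
    if d0_used == 0:
        post = s2
    elif math.isinf(d0_used):
        post = np.full_like(s2, s0sq)
    else:
        post = (d0_used * s0sq + d * s2) / (d0_used + d)
    se = np.sqrt(post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        # degenerate zero-variance features: infinitely significant when the
        # means differ, null otherwise
        t = np.where(
            se > 0,
            lfc / se,
            np.where(lfc == 0.0, 0.0, np.sign(lfc) * np.inf),
        )
    df_total = d if d0_used == 0 else d0_used + d
    return lfc, t, d0_used, s0sq, df_total


def _contrast_blocks(
    matrix: FeatureMatrix, contrast: Contrast
) -> tuple[np.ndarray, list[str], list[str]]:
    s_test = matrix.samples_for(contrast.genotype_test, contrast.phase)
    s_ref = matrix.samples_for(contrast.genotype_ref, contrast.phase)
    if len(s_test) < 2 or len(s_ref) < 2:
        raise ValueError(
            f"need >=2 replicates per group for {contrast}; "
            f"got {len(s_test)} vs {len(s_ref)}"
        )
    sub = matrix.values[s_test + s_ref]
    if sub.isna().any().any():
        raise ValueError(
            "matrix contains absent values in the tested samples; "
            "run impute_missing first"
        )
    return sub.to_numpy(dtype=float), s_test, s_ref


def moderated_test(
    matrix: FeatureMatrix, contrast: Contrast, d0: float | None = None
) -> pd.DataFrame:
    """Per-feature log2FC, moderated t and two-sided p for one contrast.

    ``d0`` overrides the estimated prior degrees of freedom; ``d0=0``
    disables shrinkage (ordinary t-test), ``None`` estimates it from the
    ensemble of per-feature variances.
    """
    x, s_test, s_ref = _contrast_blocks(matrix, contrast)
    n1 = len(s_test)
    lfc, t, d0_used, s0sq, df_total = _moderated_stats(
        x[:, :n1], x[:, n1:], d0
    )
    df_for_p = df_total if not math.isinf(df_total) else 1e12
    p = 2.0 * stats.t.sf(np.abs(t), df_for_p)
    out = pd.DataFrame(
        {"log2FC": lfc, "t": t, "p_value": p},
        index=matrix.values.index.copy(),
    )
    out.attrs.update(
        {"d0": d0_used, "s0_sq": s0sq, "df_total": df_total,
         "contrast": contrast}
    )
    return out


# ---------------------------------------------------------------------------
# Permutation FDR
# ---------------------------------------------------------------------------

def _label_assignments(
    n: int, n1: int, n_permutations: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Distinct relabelings of n samples into groups of n1/(n-n1), excluding
    the observed labeling (and, for balanced designs, its sign-flipped
    mirror which yields identical |t|)."""
    total = math.comb(n, n1)
    observed = frozenset(range(n1))
    mirror = frozenset(range(n1, n)) if n - n1 == n1 else None
    all_assignments = []
    for combo in itertools.combinations(range(n), n1):
        fs = frozenset(combo)
        if fs == observed or fs == mirror:
            continue
        if mirror is not None and frozenset(range(n)) - fs in {
            frozenset(a) for a in all_assignments
        }:
            continue  # complement duplicates |t| in balanced designs
        all_assignments.append(np.array(combo))
    n_distinct = len(all_assignments)
    if n_distinct == 0:
        raise ValueError("no non-trivial label permutations exist")
    if n_distinct <= n_permutations:
        if n_distinct < n_permutations:
            warnings.warn(
                f"only {n_distinct} distinct label permutations available "
                f"({n_permutations} requested); using all of them",
                stacklevel=3,
            )
        return all_assignments
    idx = rng.choice(n_distinct, size=n_permutations, replace=False)
    return [all_assignments[i] for i in idx]


def permutation_fdr(
    matrix: FeatureMatrix,
    contrast: Contrast,
    n_permutations: int = 200,
    seed: int = 0,
    d0: float | None = None,
) -> pd.DataFrame:
    """Moderated test plus permutation-based q-values.

    For each observed |t| threshold, the expected number of null
    exceedances is the median over genotype-label permutations (within the
    tested phase) of the count of permuted |t| values above the threshold;
    q is that count over the observed count, made non-increasing in |t| and
    clipped to [0, 1].
    """
    results = moderated_test(matrix, contrast, d0=d0)
    x, s_test, s_ref = _contrast_blocks(matrix, contrast)
    n1, n = len(s_test), len(s_test) + len(s_ref)
    rng = np.random.default_rng(seed)
    assignments = _label_assignments(n, n1, n_permutations, rng)

    obs_abs = np.abs(results["t"].to_numpy())
    order = np.argsort(-obs_abs, kind="stable")
    sorted_abs = obs_abs[order]

    counts = np.empty((len(assignments), len(sorted_abs)))
    cols = np.arange(n)
    for b, idx1 in enumerate(assignments):
        idx2 = np.setdiff1d(cols, idx1)
        _, t_perm, _, _, _ = _moderated_stats(x[:, idx1], x[:, idx2], d0)
        null_sorted = np.sort(np.abs(t_perm))
        # null values >= threshold, ties counted as exceedances
        counts[b] = len(null_sorted) - np.searchsorted(
            null_sorted, sorted_abs, side="left"
        )
    null_exceed = np.median(counts, axis=0)
    obs_exceed = np.arange(1, len(sorted_abs) + 1, dtype=float)
    raw_q = null_exceed / np.maximum(obs_exceed, 1.0)
    # monotonize: a more extreme |t| can never have a larger q
    q_sorted = np.minimum.accumulate(raw_q[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = np.clip(q_sorted, 0.0, 1.0)

    out = results.copy()
    out["q_value"] = q
    out.attrs["n_permutations_used"] = len(assignments)
    return out


# ---------------------------------------------------------------------------
# Calling and clustering
# ---------------------------------------------------------------------------

def call_features(
    results: pd.DataFrame,
    fold_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Attach reduced/enhanced/unchanged calls at the stated thresholds."""
    if fold_threshold <= 0:
        raise ValueError("fold_threshold must be positive")
    if "q_value" not in results.columns:
        raise ValueError("q_values not computed; run permutation_fdr first")
    cut = math.log2(fold_threshold)
    lfc, q = results["log2FC"], results["q_value"]
    call = np.where(
        (lfc <= -cut) & (q < fdr_threshold),
        CALL_REDUCED,
        np.where((lfc >= cut) & (q < fdr_threshold), CALL_ENHANCED, CALL_UNCHANGED),
    )
    out = results.copy()
    out["call"] = call
    out.attrs.update(results.attrs)
    out.attrs.update(
        {"fold_threshold": fold_threshold, "fdr_threshold": fdr_threshold}
    )
    return out


def differential_analysis(
    matrix: FeatureMatrix,
    contrast: Contrast,
    fold_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
    n_permutations: int = 200,
    seed: int = 0,
    d0: float | None = None,
    normalize: bool = True,
    impute: bool = True,
) -> pd.DataFrame:
    """Full per-layer chain: normalize, impute, test, permutation FDR, call."""
    m = median_normalize(matrix) if normalize else matrix
    if impute and m.values.isna().any().any():
        m = impute_missing(m, seed=seed)
    results = permutation_fdr(m, contrast, n_permutations, seed=seed, d0=d0)
    return call_features(results, fold_threshold, fdr_threshold)


def kmeans_de_clusters(
    de_matrix: FeatureMatrix | pd.DataFrame,
    k: int = 4,
    seed: int = 0,
    n_restarts: int = 50,
) -> pd.DataFrame:
    """Cluster DE features on row-standardized profiles with k-means.

    Profiles are z-scored per feature across samples (Euclidean k-means on
    z-scores = clustering by profile shape).  Clusters are renumbered 1..k
    in decreasing size order.  Returns one row per feature with its cluster
    index; per-cluster mean z-profiles (averaged within genotype-phase
    groups when metadata is available) are attached as ``attrs['profiles']``.
    """
    from sklearn.cluster import KMeans

    if isinstance(de_matrix, FeatureMatrix):
        values, meta = de_matrix.values, de_matrix.sample_metadata
    else:
        values, meta = de_matrix, None
    if values.isna().any().any():
        raise ValueError("DE matrix must be complete (impute first)")
    if k > len(values):
        raise ValueError(f"k={k} exceeds the {len(values)} features")
    z = values.sub(values.mean(axis=1), axis=0)
    sd = values.std(axis=1, ddof=0).replace(0.0, 1.0)
    z = z.div(sd, axis=0)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(z.to_numpy())
    sizes = pd.Series(labels).value_counts()
    rank = {old: new + 1 for new, old in enumerate(sizes.index)}
    cluster = np.array([rank[l] for l in labels])
    out = pd.DataFrame({"cluster": cluster}, index=values.index.copy())
    profiles = {}
    for c in range(1, k + 1):
        prof = z.loc[out["cluster"] == c]
        if meta is not None:
            groups = meta["genotype"] + "_" + meta["phase"]
            profiles[c] = prof.T.groupby(groups.to_numpy()).mean().T.mean(axis=0)
        else:
            profiles[c] = prof.mean(axis=0)
    out.attrs["profiles"] = profiles
    out.attrs["inertia"] = float(km.inertia_)
    return out
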