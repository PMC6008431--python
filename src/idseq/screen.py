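"""Screen-level analytics for kinase-inhibitor probe panels.

The differential model yields, per probe (inhibitor treatment) and molecular
phenotype (antibody), a signed p-value.  This module aggregates that
probes × phenotypes matrix: principal components summarise joint phenotype
responses; PCs are annotated by correlation with the phenotypes; top-versus-
bottom decile contrasts characterise the extremes of a PC; probe sets per
kinase are assigned from a probes × kinases %-inhibition matrix by robust
outlier statistics; a weighted Kolmogorov-Smirnov enrichment test with a
label-permutation null asks which kinase probe sets concentrate at one end of
a PC ranking; and per-set mean effect profiles support mechanism comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

MAD_SCALE = 1.4826  # MAD -> sd for normal data


@dataclass
class ScreenMatrix:
    """Probes × phenotypes matrix of signed p-values (or model estimates)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values)

    @property
    def probes(self) -> list[str]:
        return list(self.values.index.astype(str))

    @property
    def phenotypes(self) -> list[str]:
        return list(self.values.columns.astype(str))

    def require_complete(self) -> None:
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            bad = self.values.columns[self.values.isna().any() | ~np.isfinite(self.values).all()]
            raise ValueError(
                "screen matrix has missing/non-finite entries (e.g. in "
                f"{list(bad[:5])}); impute explicitly before PCA"
            )


@dataclass
class PCAResult:
    """Scores, loadings and variance shares of a screen PCA."""

    scores: pd.DataFrame          # probes × k
    loadings: pd.DataFrame        # phenotypes × k
    variance_explained: np.ndarray  # k proportions of total variance
    center: np.ndarray = field(default=None, repr=False)
    scale: np.ndarray | None = field(default=None, repr=False)


def screen_pca(matrix: ScreenMatrix | pd.DataFrame, k: int, *, scale: bool = False) -> PCAResult:
    """SVD-based PCA of the signed-p matrix.

    Columns (phenotypes) are mean-centred; unit-variance scaling is optional
    because signed p-values already share a scale.  Deterministic up to sign;
    the sign of each component is fixed so its largest-magnitude loading is
    positive.
    """
    if not isinstance(matrix, ScreenMatrix):
        matrix = ScreenMatrix(matrix)
    matrix.require_complete()
    X = matrix.values.to_numpy(dtype=float)
    n, p = X.shape
    if not 1 <= k <= min(n, p):
        raise ValueError(f"k must be in [1, {min(n, p)}], got {k}")
    center = X.mean(axis=0)
    Xc = X - center
    sd = None
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = float(np.sum(s**2))
    # sign convention: largest-|loading| entry positive per component
    for j in range(k):
        i_max = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    pcs = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame((U[:, :k] * s[:k]), index=matrix.values.index, columns=pcs)
    loadings = pd.DataFrame(Vt[:k].T, index=matrix.values.columns, columns=pcs)
    var_exp = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    return PCAResult(scores, loadings, var_exp, center=center, scale=sd)


def annotate_pcs(
    matrix: ScreenMatrix | pd.DataFrame, pca: PCAResult, top_k: int | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Correlate each phenotype with each PC and cluster the combined set.

    Returns the phenotypes × PCs Pearson correlation table and the leaf order
    of an average-linkage clustering (distance 1 - r) of phenotype columns and
    PC score vectors together — the view used to spot which phenotypes travel
    with which component.
    """
    if not isinstance(matrix, ScreenMatrix):
        matrix = ScreenMatrix(matrix)
    pcs = list(pca.scores.columns[: top_k or pca.scores.shape[1]])
    X = matrix.values.to_numpy(dtype=float)
    S = pca.scores[pcs].to_numpy(dtype=float)
    corr = np.zeros((X.shape[1], len(pcs)))
    for i in range(X.shape[1]):
        x = X[:, i]
        if np.std(x) == 0:
            warnings.warn(f"phenotype {matrix.phenotypes[i]!r} is constant; correlation set to 0")
            continue
        for j in range(len(pcs)):
            corr[i, j] = np.corrcoef(x, S[:, j])[0, 1]
    table = pd.DataFrame(corr, index=matrix.values.columns, columns=pcs)

    combined = np.column_stack([X, S])
    names = matrix.phenotypes + pcs
    keep = combined.std(axis=0) > 0
    cmat = np.corrcoef(combined[:, keep], rowvar=False)
    dist = np.clip(1.0 - cmat, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    order_kept = hierarchy.leaves_list(
        hierarchy.average(squareform(dist, checks=False))
    )
    kept_names = [n for n, k_ in zip(names, keep) if k_]
    order = [kept_names[i] for i in order_kept] + [n for n, k_ in zip(names, keep) if not k_]
    return table, order


def decile_contrast(
    values: ScreenMatrix | pd.DataFrame,
    pc_scores: pd.Series,
    fraction: float = 0.10,
    alpha: float = 0.01,
    fdr: float = 0.01,
) -> pd.DataFrame:
    """Welch t-test per phenotype between the top and bottom ``fraction`` of
    probes ranked by ``pc_scores``; BH q-values; significance requires
    p < alpha and q < fdr.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    if not isinstance(values, ScreenMatrix):
        values = ScreenMatrix(values)
    df = values.values
    scores = pc_scores.loc[df.index]
    # deterministic tie-break: probe id lexicographic within equal scores
    order = scores.iloc[
        np.lexsort((df.index.astype(str), -scores.to_numpy(dtype=float)))
    ]
    m = max(int(np.floor(fraction * len(df))), 1)
    top_ids = order.index[:m]
    bot_ids = order.index[-m:]
    rows = []
    for phen in df.columns:
        top = df.loc[top_ids, phen].to_numpy(dtype=float)
        bot = df.loc[bot_ids, phen].to_numpy(dtype=float)
        top, bot = top[np.isfinite(top)], bot[np.isfinite(bot)]
        if len(top) < 3 or len(bot) < 3:
            warnings.warn(f"phenotype {phen!r} skipped: group size < 3")
            continue
        if np.array_equal(np.sort(top), np.sort(bot)):
            t, p = 0.0, 1.0
        elif top.std(ddof=1) == 0 and bot.std(ddof=1) == 0:
            t, p = (0.0, 1.0) if top.mean() == bot.mean() else (np.inf, 0.0)
        else:
            t, p = stats.ttest_ind(top, bot, equal_var=False)
        diff = top.mean() - bot.mean()
        rows.append(
            dict(
                phenotype=phen,
                t_stat=float(t),
                p_value=float(p),
                mean_top=float(top.mean()),
                mean_bottom=float(bot.mean()),
                direction=int(np.sign(diff)),
            )
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out["significant"] = (out["p_value"] < alpha) & (out["q_value"] < fdr)
    return out


@dataclass
class ProbeSet:
    """Probes assigned to one kinase by outlier statistics on % inhibition."""

    kinase: str
    members: list[str]
    inhibition: pd.Series      # % inhibition per member
    p_values: pd.Series        # assignment p per member

    def __post_init__(self) -> None:
        bad = self.inhibition[(self.inhibition < 0) | (self.inhibition > 100)]
        if len(bad):
            raise ValueError(f"% inhibition outside [0, 100] for {list(bad.index)}")

    def __len__(self) -> int:
        return len(self.members)


def assign_probe_sets(
    inhibition: pd.DataFrame, alpha: float = 0.01, min_members: int = 0
) -> list[ProbeSet]:
    """Assign inhibitory probes to each kinase by robust outlier statistics.

    Per kinase column, the robust z-score (x - median) / (MAD * 1.4826) is
    converted to an upper-tail normal p; probes with p < alpha form the set.
    A column whose MAD is zero but which is not constant falls back to the
    mean/sd z-score; an all-constant column yields an empty set with a warning.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    vals = inhibition.to_numpy(dtype=float)
    if np.nanmin(vals) < 0 or np.nanmax(vals) > 100:
        raise ValueError("% inhibition must lie in [0, 100]")
    sets = []
    for kinase in inhibition.columns:
        x = inhibition[kinase].astype(float)
        med = x.median()
        mad = float(stats.median_abs_deviation(x, nan_policy="omit"))
        if mad > 0:
            z = (x - med) / (mad * MAD_SCALE)
        else:
            sd = x.std(ddof=1)
            if not sd > 0:
                warnings.warn(f"kinase {kinase!r}: constant inhibition column, empty set")
                sets.append(
                    ProbeSet(str(kinase), [], x.iloc[0:0], x.iloc[0:0].astype(float))
                )
                continue
            z = (x - x.mean()) / sd
        p = pd.Series(stats.norm.sf(z), index=x.index)
        members = sorted(p.index[p < alpha].astype(str))
        if len(members) < min_members:
            continue
        sets.append(ProbeSet(str(kinase), members, x.loc[members], p.loc[members]))
    return sets


@dataclass
class EnrichmentResult:
    """Permutation-tested enrichment of one probe set in a PC ranking."""

    kinase: str
    es: float
    p_value: float
    q_value: float
    leading_edge: list[str]
    n_members: int


def _ranked(pc_scores: pd.Series) -> pd.Series:
    """Probes sorted by score descending, ties broken by probe id."""
    idx = np.lexsort((pc_scores.index.astype(str), -pc_scores.to_numpy(dtype=float)))
    return pc_scores.iloc[idx]


def enrichment_score(
    ranked_scores: np.ndarray, member_pos: np.ndarray, weight: float = 1.0
) -> tuple[float, int]:
    """Weighted Kolmogorov-Smirnov running-sum enrichment score.

    ``member_pos`` are 0-based positions of the set members in the ranking.
    Returns (ES, extremum position); ES is the running-sum deviation of
    largest magnitude, positive when the set concentrates at the top.
    """
    n = len(ranked_scores)
    pos = np.sort(np.asarray(member_pos))
    m = len(pos)
    if m == 0 or m >= n:
        raise ValueError("set must be a non-empty strict subset of the ranking")
    w = np.abs(ranked_scores[pos]) ** weight
    nr = w.sum()
    if nr == 0:
        w = np.ones(m)
        nr = float(m)
    hits = np.cumsum(w) / nr
    miss_rate = 1.0 / (n - m)
    # running sum just after each hit, and just before each hit
    after = hits - (pos + 1 - np.arange(1, m + 1)) * miss_rate
    before = np.concatenate(([0.0], hits[:-1])) - (pos - np.arange(m)) * miss_rate
    i_max = int(np.argmax(after))
    i_min = int(np.argmin(before))
    if after[i_max] >= -before[i_min]:
        return float(after[i_max]), int(pos[i_max])
    return float(before[i_min]), int(pos[i_min])


def gsea(
    pc_scores: pd.Series,
    sets: list[ProbeSet],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
    min_size: int = 3,
) -> list[EnrichmentResult]:
    """Probe-set enrichment along a PC ranking with a label-permutation null.

    The null resamples member labels: for a set of m members, m probes are
    drawn uniformly from the ranking ``n_perm`` times.  The p-value is
    one-sided within the sign of the observed ES against same-signed
    permutation scores (so null p-values are uniform); BH FDR across sets.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    ranked = _ranked(pc_scores)
    ranked_ids = ranked.index.astype(str)
    id_pos = {pid: i for i, pid in enumerate(ranked_ids)}
    scores_arr = ranked.to_numpy(dtype=float)
    n = len(scores_arr)

    results = []
    pvals = []
    for ps in sets:
        missing = [mbr for mbr in ps.members if mbr not in id_pos]
        if missing:
            raise ValueError(
                f"probe set {ps.kinase!r} has members absent from the ranking: {missing[:5]}"
            )
        if len(ps) < min_size:
            warnings.warn(f"probe set {ps.kinase!r} smaller than {min_size}; skipped")
            continue
        pos = np.array([id_pos[mbr] for mbr in ps.members])
        es, ext = enrichment_score(scores_arr, pos, weight)
        m = len(pos)
        perm_es = np.empty(n_perm)
        for b in range(n_perm):
            perm_pos = rng.choice(n, size=m, replace=False)
            perm_es[b], _ = enrichment_score(scores_arr, perm_pos, weight)
        if es >= 0:
            pool = perm_es[perm_es >= 0]
            p = (1.0 + np.sum(pool >= es)) / (1.0 + len(pool))
        else:
            pool = perm_es[perm_es < 0]
            p = (1.0 + np.sum(pool <= es)) / (1.0 + len(pool))
        if es >= 0:
            leading = [pid for pid in ranked_ids[: ext + 1] if pid in set(ps.members)]
        else:
            leading = [pid for pid in ranked_ids[ext:] if pid in set(ps.members)]
        results.append(
            EnrichmentResult(ps.kinase, es, float(p), np.nan, leading, m)
        )
        pvals.append(float(p))
    if results:
        q = multipletests(pvals, method="fdr_bh")[1]
        for r, qv in zip(results, q):
            r.q_value = float(qv)
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        dict(
            kinase=[r.kinase for r in results],
            es=[r.es for r in results],
            p_value=[r.p_value for r in results],
            q_value=[r.q_value for r in results],
            n_members=[r.n_members for r in results],
            leading_edge=[",".join(r.leading_edge) for r in results],
        )
    )


def kinase_profiles(
    estimates: pd.DataFrame, sets: list[ProbeSet]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean model estimate per (kinase set, phenotype), with standard errors.

    Returns (means, sems), both kinases × phenotypes; a singleton set has NaN
    standard errors.
    """
    means, sems = {}, {}
    for ps in sets:
        if not ps.members:
            continue
        missing = [mbr for mbr in ps.members if mbr not in estimates.index]
        if missing:
            raise ValueError(f"set {ps.kinase!r}: members not screened: {missing[:5]}")
        sub = estimates.loc[ps.members]
        means[ps.kinase] = sub.mean(axis=0)
        if len(ps) > 1:
            sems[ps.kinase] = sub.std(axis=0, ddof=1) / np.sqrt(len(ps))
        else:
            sems[ps.kinase] = pd.Series(np.nan, index=estimates.columns)
    mean_df = pd.DataFrame(means).T
    sem_df = pd.DataFrame(sems).T
    return mean_df, sem_df


def profile_cluster_compare(
    profiles: pd.DataFrame,
    estimates: pd.DataFrame,
    sets: list[ProbeSet],
    reference_kinase: str,
    k_clusters: int,
    seed: int = 0,
    n_restarts: int = 50,
) -> tuple[pd.Series, pd.DataFrame]:
    """K-means clustering of kinase profiles plus per-phenotype Welch t-tests
    of each kinase's member-probe estimates against the reference kinase's.

    Returns (labels indexed by kinase, kinase × phenotype p-value table).
    """
    if k_clusters >= len(profiles):
        raise ValueError("k_clusters must be smaller than the number of kinases")
    X = profiles.to_numpy(dtype=float)
    if np.allclose(X, X[0]):
        warnings.warn("identical profiles; returning a single cluster")
        labels = pd.Series(0, index=profiles.index)
    else:
        km = KMeans(
            n_clusters=k_clusters, n_init=n_restarts, random_state=seed
        ).fit(X)
        labels = pd.Series(km.labels_, index=profiles.index)

    by_kinase = {ps.kinase: ps for ps in sets}
    if reference_kinase not in by_kinase:
        raise ValueError(f"reference kinase {reference_kinase!r} has no probe set")
    ref = estimates.loc[by_kinase[reference_kinase].members]
    pmat = {}
    for kinase in profiles.index:
        if kinase not in by_kinase:
            continue
        sub = estimates.loc[by_kinase[kinase].members]
        ps_row = []
        for phen in estimates.columns:
            a = sub[phen].to_numpy(dtype=float)
            b = ref[phen].to_numpy(dtype=float)
            if kinase == reference_kinase or (
                np.array_equal(np.sort(a), np.sort(b))
            ):
                ps_row.append(1.0)
                continue
            if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
                ps_row.append(1.0 if a.mean() == b.mean() else 0.0)
                continue
            ps_row.append(float(stats.ttest_ind(a, b, equal_var=False)[1]))
        pmat[kinase] = pd.Series(ps_row, index=estimates.columns)
    return labels, pd.DataFrame(pmat).T
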