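"""Group-level inference.

* cluster-based permutation test on channel x time-bin HbO responses
  (max-sum cluster mass statistic over a spatio-temporal adjacency, null
  from random relabelings of subjects);
* Welch t-tests on hemisphere-mean AUC with descriptive medians/IQRs;
* balanced mixed-design (split-plot) ANOVA for the GFP and template
  projection measures, computed from sums of squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import sparse, stats as sps


# --------------------------------------------------------------------------
# epoch downsampling


def downsample_epochs(
    epochs: np.ndarray,
    fs_hz: float,
    window_s: tuple[float, float] = (-5.0, 25.0),
    bin_s: float = 1.0,
) -> np.ndarray:
    """Average native samples into 1-s bins over the [-5, +25) s window.

    ``epochs`` is (... , n_samples) on the canonical epoch grid
    ``window[0] + k / fs``; bin b collects samples with time in
    [window[0] + b, window[0] + b + 1).  Returns (..., 30) for the default
    window.
    """
    span = window_s[1] - window_s[0]
    n_bins = int(round(span / bin_s))
    if abs(n_bins * bin_s - span) > 1e-9:
        raise ValueError("window length must be a multiple of the bin size")
    n = epochs.shape[-1]
    t = window_s[0] + np.arange(n) / fs_hz
    out = np.empty(epochs.shape[:-1] + (n_bins,))
    for b in range(n_bins):
        sel = (t >= window_s[0] + b * bin_s) & (t < window_s[0] + (b + 1) * bin_s)
        if not sel.any():
            raise ValueError(f"bin {b} holds no samples")
        out[..., b] = epochs[..., sel].mean(axis=-1)
    return out


# --------------------------------------------------------------------------
# cluster-based permutation test


@dataclass
class Cluster:
    members: list[tuple[int, int]]  # (channel index, bin index)
    mass: float
    p_value: float


@dataclass
class ClusterTestResult:
    clusters: list[Cluster]
    t_map: np.ndarray  # channel x bin observed t
    threshold_map: np.ndarray  # per-cell critical |t|
    n_permutations: int
    exhaustive: bool
    forming_alpha: float

    @property
    def min_p(self) -> float:
        return min((c.p_value for c in self.clusters), default=1.0)


def _welch_t(a: np.ndarray, b: np.ndarray):
    """Vectorized two-sample Welch t and Welch-Satterthwaite df over axis 0."""
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(0), b.mean(0)
    va, vb = a.var(0, ddof=1), b.var(0, ddof=1)
    sa, sb = va / na, vb / nb
    denom = np.sqrt(sa + sb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / denom
        df = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    t = np.where(denom == 0, 0.0, t)
    df = np.where(np.isfinite(df), df, na + nb - 2)
    return t, df


def _cell_graph(n_channels: int, n_bins: int, adjacency: np.ndarray) -> sparse.csr_matrix:
    """Sparse graph over (channel, bin) cells: temporal edges between
    consecutive bins of one channel, spatial edges between adjacent channels
    within one bin."""
    rows, cols = [], []
    def cell(c, b):
        return c * n_bins + b

    for c in range(n_channels):
        for b in range(n_bins - 1):
            rows.append(cell(c, b))
            cols.append(cell(c, b + 1))
    ch_pairs = np.argwhere(np.triu(adjacency, 1))
    for c1, c2 in ch_pairs:
        for b in range(n_bins):
            rows.append(cell(c1, b))
            cols.append(cell(c2, b))
    n = n_channels * n_bins
    g = sparse.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    g = g + g.T
    return g.tocsr()


def _cluster_masses(t_flat, thr_flat, graph) -> tuple[list[list[int]], list[float]]:
    """Connected suprathreshold clusters with sign agreement; returns member
    lists and signed masses."""
    members_all, masses = [], []
    for sign in (1, -1):
        mask = sign * t_flat > thr_flat
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            continue
        sub = graph[idx][:, idx]
        n_comp, labels = sparse.csgraph.connected_components(sub, directed=False)
        for k in range(n_comp):
            mem = idx[labels == k]
            members_all.append(mem.tolist())
            masses.append(float(t_flat[mem].sum()))
    return members_all, masses


def _max_mass(t_flat, thr_flat, graph) -> float:
    _, masses = _cluster_masses(t_flat, thr_flat, graph)
    return max((abs(m) for m in masses), default=0.0)


def cluster_permutation_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    adjacency: np.ndarray,
    forming_alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> ClusterTestResult:
    """Two-sample cluster-based permutation test on subject x channel x bin
    data (Maris-Oostenveld style).

    Cells with two-sided Welch |t| above the per-cell critical value at
    ``forming_alpha`` enter clusters; clusters are maximal connected sets
    under (same channel, consecutive bins) or (same bin, spatially adjacent
    channels) with a common t sign.  The cluster statistic is the mass (sum
    of member t values); the null distribution is the maximum |mass| over
    random relabelings of subjects — exhaustive when no more than ``n_perm``
    distinct relabelings exist, otherwise ``n_perm`` seeded draws.  p-values
    use the add-one estimator.
    """
    a, b = np.asarray(group_a, float), np.asarray(group_b, float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("groups must share channel x bin shape")
    n_ch, n_bins = a.shape[1], a.shape[2]
    adjacency = np.asarray(adjacency, bool)
    if adjacency.shape != (n_ch, n_ch):
        raise ValueError("adjacency must be n_channels x n_channels")
    graph = _cell_graph(n_ch, n_bins, adjacency)

    na = a.shape[0]
    pooled = np.concatenate([a, b]).reshape(na + b.shape[0], -1)
    n_tot = pooled.shape[0]

    def stat(idx_a):
        sel = np.zeros(n_tot, bool)
        sel[list(idx_a)] = True
        t, df = _welch_t(pooled[sel], pooled[~sel])
        thr = sps.t.ppf(1 - forming_alpha / 2, df)
        return t, thr

    t_obs, thr_obs = stat(range(na))
    members, masses = _cluster_masses(t_obs, thr_obs, graph)

    n_distinct = comb(n_tot, na)
    null = []
    if n_distinct <= n_perm:
        exhaustive = True
        for idx_a in combinations(range(n_tot), na):
            t, thr = stat(idx_a)
            null.append(_max_mass(t, thr, graph))
    else:
        exhaustive = False
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            idx_a = rng.permutation(n_tot)[:na]
            t, thr = stat(idx_a)
            null.append(_max_mass(t, thr, graph))
    null = np.asarray(null)

    clusters = []
    for mem, mass in zip(members, masses):
        p = (1 + int((null >= abs(mass)).sum())) / (1 + len(null))
        clusters.append(
            Cluster(
                members=[(m // n_bins, m % n_bins) for m in mem],
                mass=mass,
                p_value=p,
            )
        )
    clusters.sort(key=lambda c: -abs(c.mass))
    return ClusterTestResult(
        clusters=clusters,
        t_map=t_obs.reshape(n_ch, n_bins),
        threshold_map=thr_obs.reshape(n_ch, n_bins),
        n_permutations=len(null),
        exhaustive=exhaustive,
        forming_alpha=forming_alpha,
    )


# --------------------------------------------------------------------------
# hemisphere AUC comparison


@dataclass
class AucComparison:
    hemisphere: str
    t: float
    p: float
    df: float
    median_a: float
    median_b: float
    iqr_a: float
    iqr_b: float


def compare_auc(
    auc_a: dict[str, np.ndarray], auc_b: dict[str, np.ndarray]
) -> dict[str, AucComparison]:
    """Welch two-sample t per hemisphere on subject hemisphere-mean AUCs,
    with group medians and interquartile ranges.

    ``auc_a`` / ``auc_b`` map hemisphere ("L"/"R") to per-subject values.
    """
    out = {}
    for h in auc_a:
        xa, xb = np.asarray(auc_a[h], float), np.asarray(auc_b[h], float)
        if xa.size < 2 or xb.size < 2:
            raise ValueError(f"need >= 2 subjects per group (hemisphere {h})")
        if np.var(xa) == 0 and np.var(xb) == 0 and xa.mean() == xb.mean():
            t, p, df = 0.0, 1.0, float(xa.size + xb.size - 2)
        else:
            res = sps.ttest_ind(xa, xb, equal_var=False)
            t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
        q1a, q3a = np.percentile(xa, [25, 75])
        q1b, q3b = np.percentile(xb, [25, 75])
        out[h] = AucComparison(
            hemisphere=h,
            t=t,
            p=p,
            df=df,
            median_a=float(np.median(xa)),
            median_b=float(np.median(xb)),
            iqr_a=float(q3a - q1a),
            iqr_b=float(q3b - q1b),
        )
    return out


# --------------------------------------------------------------------------
# mixed (split-plot) ANOVA


@dataclass
class AnovaRow:
    effect: str
    f: float
    df_num: int
    df_den: int
    p: float


def _f_row(name, ss_eff, df_eff, ss_err, df_err) -> AnovaRow:
    ms_eff = ss_eff / df_eff
    ms_err = ss_err / df_err
    if ss_eff <= 1e-24:
        f = 0.0
    elif ms_err <= 1e-24:
        f = np.inf
    else:
        f = ms_eff / ms_err
    p = 1.0 if f == 0 else float(sps.f.sf(f, df_eff, df_err))
    return AnovaRow(effect=name, f=float(f), df_num=int(df_eff), df_den=int(df_err), p=p)


def mixed_anova(
    values: np.ndarray,
    groups: np.ndarray,
    within_names: tuple[str, ...] = ("peak", "repetition"),
    group_name: str = "group",
) -> list[AnovaRow]:
    """Balanced mixed-design ANOVA with one between-subject factor and one
    or two within-subject factors.

    ``values`` is subject x levels(A) [x levels(B)]; ``groups`` assigns each
    subject to a between-subject group.  Every group must have >= 2 subjects
    and full cells (no imputation).  Returns rows for the between effect,
    the within main effects, and all interactions, each tested against its
    own error stratum (subject, A x subject, B x subject, A x B x subject,
    all nested in group).
    """
    y = np.asarray(values, float)
    groups = np.asarray(groups)
    if y.ndim == 2:
        y = y[:, :, None]
        names = (within_names[0],)
    elif y.ndim == 3:
        names = tuple(within_names[:2])
    else:
        raise ValueError("values must be subject x A or subject x A x B")
    if not np.isfinite(y).all():
        raise ValueError("unbalanced design: missing cells are not supported")
    n_sub, a_lv, b_lv = y.shape
    glabels, gidx = np.unique(groups, return_inverse=True)
    n_g = len(glabels)
    counts = np.bincount(gidx)
    if counts.min() < 2:
        raise ValueError("need at least 2 subjects per group")

    grand = y.mean()
    m_s = y.mean(axis=(1, 2))  # subject means
    m_g = np.array([m_s[gidx == g].mean() for g in range(n_g)])
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_ga = np.stack([y[gidx == g].mean(axis=(0, 2)) for g in range(n_g)])
    m_gb = np.stack([y[gidx == g].mean(axis=(0, 1)) for g in range(n_g)])
    m_ab = y.mean(axis=0)
    m_gab = np.stack([y[gidx == g].mean(axis=0) for g in range(n_g)])
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)

    cell = a_lv * b_lv
    rows: list[AnovaRow] = []

    # between stratum
    ss_group = cell * float(np.sum(counts * (m_g - grand) ** 2))
    ss_sw = cell * float(np.sum((m_s - m_g[gidx]) ** 2))
    rows.append(_f_row(group_name, ss_group, n_g - 1, ss_sw, n_sub - n_g))

    # within factor A stratum
    ss_a = n_sub * b_lv * float(np.sum((m_a - grand) ** 2))
    ss_ag = b_lv * float(
        np.sum(counts[:, None] * (m_ga - m_g[:, None] - m_a[None, :] + grand) ** 2)
    )
    resid_a = m_sa - m_s[:, None] - m_ga[gidx] + m_g[gidx, None]
    ss_as = b_lv * float(np.sum(resid_a**2))
    df_as = (a_lv - 1) * (n_sub - n_g)
    rows.append(_f_row(names[0], ss_a, a_lv - 1, ss_as, df_as))
    rows.append(_f_row(f"{names[0]}*{group_name}", ss_ag, (a_lv - 1) * (n_g - 1), ss_as, df_as))

    if b_lv > 1:
        ss_b = n_sub * a_lv * float(np.sum((m_b - grand) ** 2))
        ss_bg = a_lv * float(
            np.sum(counts[:, None] * (m_gb - m_g[:, None] - m_b[None, :] + grand) ** 2)
        )
        resid_b = m_sb - m_s[:, None] - m_gb[gidx] + m_g[gidx, None]
        ss_bs = a_lv * float(np.sum(resid_b**2))
        df_bs = (b_lv - 1) * (n_sub - n_g)
        rows.append(_f_row(names[1], ss_b, b_lv - 1, ss_bs, df_bs))
        rows.append(
            _f_row(f"{names[1]}*{group_name}", ss_bg, (b_lv - 1) * (n_g - 1), ss_bs, df_bs)
        )

        ss_ab = n_sub * float(
            np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
        )
        ss_abg = float(
            np.sum(
                counts[:, None, None]
                * (
                    m_gab
                    - m_ga[:, :, None]
                    - m_gb[:, None, :]
                    + m_g[:, None, None]
                    - m_ab[None]
                    + m_a[None, :, None]
                    + m_b[None, None, :]
                    - grand
                )
                ** 2
            )
        )
        resid_ab = (
            y
            - m_sa[:, :, None]
            - m_sb[:, None, :]
            + m_s[:, None, None]
            - m_gab[gidx]
            + m_ga[gidx][:, :, None]
            + m_gb[gidx][:, None, :]
            - m_g[gidx][:, None, None]
        )
        ss_abs = float(np.sum(resid_ab**2))
        df_abs = (a_lv - 1) * (b_lv - 1) * (n_sub - n_g)
        ab = f"{names[0]}*{names[1]}"
        rows.append(_f_row(ab, ss_ab, (a_lv - 1) * (b_lv - 1), ss_abs, df_abs))
        rows.append(
            _f_row(f"{ab}*{group_name}", ss_abg, (a_lv - 1) * (b_lv - 1) * (n_g - 1), ss_abs, df_abs)
        )
    return rows
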