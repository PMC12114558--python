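"""Environment–community association statistics.

Spearman/Pearson correlation grids, Mantel permutation tests between distance
matrices, redundancy analysis (RDA) with marginal per-variable explained
fractions, and one-way ANOVA with Tukey HSD compact letter displays.

Conventions: Spearman is mid-rank ties then Pearson on ranks, with the usual
t approximation (n−2 df) for p-values. The Mantel test is one-sided
(positive association) with p = (1 + #{r_perm ≥ r_obs}) / (1 + n_perm).
No multiple-testing correction is applied to correlation grids by default;
Benjamini–Hochberg is available behind a flag.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from ._seeds import child_rng


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int
    method: str
    seed: int


@dataclass(frozen=True)
class RdaResult:
    """Marginal explained fractions plus the constrained ordination."""

    explained: pd.Series          # % per explanatory variable, ranked desc
    sample_scores: pd.DataFrame   # constrained axis scores
    total_constrained: float      # fraction of total variance, full model
    dropped: tuple[str, ...] = ()


@dataclass(frozen=True)
class GroupComparison:
    summary: pd.DataFrame  # index group: mean, sd, n, letters
    alpha: float
    anova_f: float
    anova_p: float


def correlation_matrix(
    X: pd.DataFrame,
    method: str = "spearman",
    bh_correct: bool = False,
) -> pd.DataFrame:
    """All-pairs correlations of a variables × samples table.

    Returns a tidy DataFrame (``var1, var2, r, p, n``) over unordered pairs.
    Pairs are computed on complete observations; constant variables yield
    missing coefficients with a warning.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be spearman|pearson")
    variables = list(X.index)
    rows = []
    for v1, v2 in itertools.combinations(variables, 2):
        pair = X.loc[[v1, v2]].T.dropna()
        n = len(pair)
        if n < 4:
            raise ValueError(f"pair ({v1}, {v2}): fewer than 4 complete samples")
        x, y = pair[v1].to_numpy(float), pair[v2].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(
                f"constant variable in pair ({v1}, {v2}); r undefined",
                stacklevel=2,
            )
            r, p = np.nan, np.nan
        elif method == "spearman":
            r, p = stats.spearmanr(x, y)
        else:
            r, p = stats.pearsonr(x, y)
        rows.append({"var1": v1, "var2": v2, "r": r, "p": p, "n": n})
    out = pd.DataFrame(rows)
    if bh_correct and len(out):
        ok = out["p"].notna()
        out.loc[ok, "p_adj"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out


def _condensed(D: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(D.shape[0], k=1)
    return D[iu]


def mantel_test(
    d1,
    d2,
    method: str = "spearman",
    n_perm: int | str = 999,
    seed: int = 0,
    alternative: str = "greater",
) -> MantelResult:
    """Permutation Mantel test between two distance matrices.

    The correlation of the upper off-diagonal vectors is compared against the
    distribution obtained by jointly permuting rows and columns of ``d2``.
    One-sided (positive association) by default. ``n_perm="exact"``
    enumerates all n!−1 nontrivial permutations (small n only).
    """
    if isinstance(d1, pd.DataFrame) and isinstance(d2, pd.DataFrame):
        missing = d1.index.symmetric_difference(d2.index)
        if len(missing):
            raise ValueError(f"sample sets differ: {list(missing)}")
        d2 = d2.loc[d1.index, d1.index]
    D1 = np.asarray(d1, dtype=float)
    D2 = np.asarray(d2, dtype=float)
    n = D1.shape[0]
    if D1.shape != (n, n) or D2.shape != (n, n):
        raise ValueError("distance matrices must be square and matching in size")
    if not (np.allclose(D1, D1.T) and np.allclose(D2, D2.T)):
        raise ValueError("distance matrices must be symmetric")
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be spearman|pearson")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError("alternative must be greater|less|two-sided")

    v1 = _condensed(D1)
    # rank once: a joint row/column permutation of D2 permutes the condensed
    # vector's entries, so ranks can be permuted through the matrix form
    if method == "spearman":
        v1 = stats.rankdata(v1)
        R2 = np.zeros_like(D2)
        iu = np.triu_indices(n, k=1)
        ranks = stats.rankdata(_condensed(D2))
        R2[iu] = ranks
        R2 = R2 + R2.T
    else:
        R2 = D2

    def corr(vec2):
        a = v1 - v1.mean()
        b = vec2 - vec2.mean()
        denom = np.sqrt((a**2).sum() * (b**2).sum())
        return float((a * b).sum() / denom) if denom > 0 else np.nan

    r_obs = corr(_condensed(R2))
    if n_perm == "exact":
        if n > 8:
            raise ValueError("exact enumeration is limited to n <= 8 samples")
        perms = [np.array(p) for p in itertools.permutations(range(n))][1:]
    else:
        rng = child_rng(seed, "mantel")
        perms = (rng.permutation(n) for _ in range(n_perm))
    exceed = total = 0
    for perm in perms:
        r_perm = corr(_condensed(R2[np.ix_(perm, perm)]))
        total += 1
        if alternative == "greater":
            exceed += r_perm >= r_obs
        elif alternative == "less":
            exceed += r_perm <= r_obs
        else:
            exceed += abs(r_perm) >= abs(r_obs)
    p = (1 + exceed) / (1 + total)
    return MantelResult(r=r_obs, p=float(p), n_perm=total, method=method, seed=seed)


def rda_explained(
    Y: pd.DataFrame,
    X: pd.DataFrame,
    standardize: bool = True,
    collinearity_tol: float = 1e-10,
) -> RdaResult:
    """Redundancy analysis of a samples × features response on explanatory
    variables (samples × variables).

    The constrained ordination is the eigen-decomposition (SVD) of the
    least-squares fitted Ŷ; each variable's explained % is computed
    marginally — fitted alone, trace(ŶᵥᵀŶᵥ)/trace(YᵀY) × 100 — and ranked
    descending, matching the simple "ranked by explains" presentation used
    for environment-vs-community comparisons.
    """
    if not Y.index.equals(X.index):
        X = X.loc[Y.index]
    n, q = X.shape
    if n < q + 2:
        raise ValueError(f"need >= {q + 2} samples for {q} explanatory variables")
    Yc = Y.to_numpy(float) - Y.to_numpy(float).mean(axis=0)
    Xm = X.to_numpy(float)
    Xm = Xm - Xm.mean(axis=0)
    if standardize:
        sd = Xm.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xm = Xm / sd

    # drop collinear columns (QR with pivoting)
    keep, dropped = [], []
    for j in range(q):
        cand = Xm[:, keep + [j]]
        if np.linalg.matrix_rank(cand, tol=collinearity_tol * max(n, q)) == len(keep) + 1:
            keep.append(j)
        else:
            dropped.append(X.columns[j])
    if dropped:
        warnings.warn(f"dropping collinear explanatory variable(s): {dropped}",
                      stacklevel=2)
    Xk = Xm[:, keep]

    total = float((Yc**2).sum())
    if total == 0:
        raise ValueError("response matrix has zero variance")

    def fitted(Xv):
        beta, *_ = np.linalg.lstsq(Xv, Yc, rcond=None)
        return Xv @ beta

    explained = {}
    for j, col in zip(keep, [X.columns[j] for j in keep]):
        Yhat_v = fitted(Xm[:, [j]])
        explained[col] = float((Yhat_v**2).sum()) / total * 100.0
    explained = pd.Series(explained).sort_values(ascending=False)

    Yhat = fitted(Xk)
    U, S, _ = np.linalg.svd(Yhat, full_matrices=False)
    n_axes = min(len(keep), (S > 1e-12 * S.max()).sum() if S.size else 0)
    scores = pd.DataFrame(
        (U[:, :n_axes] * S[:n_axes]),
        index=Y.index,
        columns=[f"RDA{i + 1}" for i in range(n_axes)],
    )
    return RdaResult(
        explained=explained,
        sample_scores=scores,
        total_constrained=float((Yhat**2).sum()) / total,
        dropped=tuple(str(d) for d in dropped),
    )


def _compact_letter_display(
    groups: list[str], different: set[tuple[str, str]]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are not significantly different; every group gets
    at least one letter.
    """
    letter_sets: list[set[str]] = [set(groups)]
    for a, b in different:
        new_sets = []
        for s in letter_sets:
            if a in s and b in s:
                new_sets.append(s - {a})
                new_sets.append(s - {b})
            else:
                new_sets.append(s)
        # absorb: drop sets contained in another
        letter_sets = [
            s
            for i, s in enumerate(new_sets)
            if s and not any(s < t or (s == t and i > j)
                             for j, t in enumerate(new_sets) if j != i)
        ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    # stable letter order: by first (in group order) member
    order = {g: i for i, g in enumerate(groups)}
    letter_sets.sort(key=lambda s: min(order[g] for g in s))
    out = {g: "" for g in groups}
    for letter, s in zip(alphabet, letter_sets):
        for g in groups:
            if g in s:
                out[g] += letter
    return out


def anova_tukey_letters(
    values,
    groups,
    alpha: float = 0.05,
) -> GroupComparison:
    """One-way ANOVA with Tukey HSD pairwise tests and letter display."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    by_group = {g: values[groups == g] for g in labels}
    thin = [g for g, v in by_group.items() if len(v) < 2]
    if thin:
        raise ValueError(f"group(s) with a single replicate: {thin}")
    f, p = stats.f_oneway(*by_group.values())
    tuk = pairwise_tukeyhsd(values, groups, alpha=alpha)
    different = set()
    for (a, b), rej in zip(
        itertools.combinations(sorted(labels, key=str), 2), tuk.reject
    ):
        if rej:
            different.add((a, b))
    letters = _compact_letter_display(labels, different)
    summary = pd.DataFrame(
        {
            "mean": {g: float(v.mean()) for g, v in by_group.items()},
            "sd": {g: float(v.std(ddof=1)) for g, v in by_group.items()},
            "n": {g: len(v) for g, v in by_group.items()},
            "letters": letters,
        }
    ).rename_axis("group")
    return GroupComparison(summary=summary, alpha=alpha, anova_f=float(f),
                           anova_p=float(p))
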