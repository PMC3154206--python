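"""Two-group empirical-Bayes linear model for log-scale expression data.

Per gene, the model estimates the log fold change between two sample
groups, shrinks the residual variance towards a common prior by an
empirical-Bayes (moderated-t) approach, and derives a moderated
t-statistic together with a raw two-sided p-value.

The variance prior is a scaled inverse-chi-square (equivalently, the
gene-wise sample variances follow a scaled F distribution around the
prior variance ``s0_sq`` with prior degrees of freedom ``d0``).  The
hyperparameters are estimated by moment matching on the log sample
variances using digamma/trigamma functions; the moderated t-statistic is
referred to a t-distribution with augmented degrees of freedom
``f* = d0 + d``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

__all__ = [
    "ExpressionMatrix",
    "GroupAssignment",
    "ModeratedFit",
    "estimate_prior",
    "trigamma_inverse",
    "moderated_t_pvalues",
    "fit_two_group",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x sample matrix of log-scale expression values.

    Values are assumed to be on the log2 scale (so a unit difference in
    group means is a two-fold expression change); this convention is
    documented, not enforced.
    """

    values: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if values.ndim != 2:
            raise ValueError(f"expression values must be 2-dimensional, got shape {values.shape}")
        m, n = values.shape
        if len(self.gene_ids) != m:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {m} rows")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} columns")
        if n < 2:
            raise ValueError("at least 2 samples required")
        dupes = _duplicates(self.gene_ids)
        if dupes:
            raise ValueError(f"duplicate gene ids: {', '.join(dupes[:10])}")
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite expression value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class GroupAssignment:
    """Per-sample group indicator taking values 1 and 2.

    Group 1 is the reference: the fitted log fold change is
    mean(group 2) - mean(group 1).  Each group needs at least two
    samples so the pooled residual variance has d = n1 + n2 - 2 >= 2
    degrees of freedom.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", labels)
        if labels.ndim != 1:
            raise ValueError("group labels must be a 1-d sequence")
        bad = set(np.unique(labels)) - {1, 2}
        if bad:
            raise ValueError(f"group labels must be 1 or 2, found {sorted(bad)}")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError(
                f"each group needs >=2 samples for variance estimation "
                f"(got n1={self.n1}, n2={self.n2})"
            )

    @property
    def n1(self) -> int:
        return int(np.sum(self.labels == 1))

    @property
    def n2(self) -> int:
        return int(np.sum(self.labels == 2))


@dataclass(frozen=True)
class ModeratedFit:
    """Result of the empirical-Bayes two-group fit.

    Attributes
    ----------
    beta_hat : per-gene estimated log fold change (log2 units).
    s2 : per-gene pooled residual variance.
    d : residual degrees of freedom, n1 + n2 - 2 (scalar).
    d0 : prior degrees of freedom (scalar, possibly ``inf``).
    s0_sq : prior variance (scalar).
    s2_post : per-gene posterior variance (d0*s0_sq + d*s2)/(d0 + d).
    unscaled_sd : design factor sqrt(1/n1 + 1/n2) (scalar).
    se_tilde : per-gene shrunken standard error sqrt(s2_post)*unscaled_sd.
    f_star : augmented degrees of freedom d0 + d (scalar, possibly ``inf``).
    t_mod : per-gene moderated t-statistic beta_hat/se_tilde.
    p_raw : per-gene two-sided raw p-value.
    gene_ids : gene identifiers, in input order.
    """

    beta_hat: np.ndarray
    s2: np.ndarray
    d: float
    d0: float
    s0_sq: float
    s2_post: np.ndarray
    unscaled_sd: float
    se_tilde: np.ndarray
    f_star: float
    t_mod: np.ndarray
    p_raw: np.ndarray
    gene_ids: tuple[str, ...] = field(default=())

    @property
    def n_genes(self) -> int:
        return self.beta_hat.shape[0]


def _duplicates(items) -> list[str]:
    seen: set[str] = set()
    dupes: list[str] = []
    for x in items:
        if x in seen and x not in dupes:
            dupes.append(x)
        seen.add(x)
    return dupes


def trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration.

    trigamma is strictly decreasing and convex on (0, inf), so Newton
    from the asymptotic start y = 0.5 + 1/x converges monotonically.
    Extreme arguments use the asymptotic expansions trigamma(y) ~ 1/y
    (y large) and trigamma(y) ~ 1/y^2 (y small).
    """
    if not np.isfinite(x) or x <= 0:
        raise ValueError(f"trigamma_inverse requires finite x > 0, got {x}")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < tol * y:
            break
    return float(y)


def estimate_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Estimate (d0, s0_sq) of the variance prior by moment matching.

    Given gene-wise sample variances ``s2`` on ``d`` residual degrees of
    freedom, fit the scaled-F model s2_j ~ s0_sq * F(d, d0) by matching
    the mean and variance of log s2:

        e_j  = log s2_j - digamma(d/2) + log(d/2)
        ebar = mean(e);  v = var(e, ddof=1) - trigamma(d/2)
        v > 0:  d0 = 2 * trigamma_inverse(v),
                s0_sq = exp(ebar + digamma(d0/2) - log(d0/2))
        v <= 0: d0 = inf, s0_sq = mean(s2)

    The infinite-d0 branch applies when the empirical dispersion of the
    log variances does not exceed the pure chi-square sampling
    dispersion trigamma(d/2).  Genes with s2 == 0 carry no usable
    log-variance information and are excluded from the moment matching
    (they are still shrunken by the caller).

    Returns
    -------
    (d0, s0_sq) with d0 > 0 (possibly ``inf``) and s0_sq > 0.
    """
    s2 = np.asarray(s2, dtype=float)
    if s2.ndim != 1:
        raise ValueError("s2 must be a 1-d vector")
    if np.any(s2 < 0) or not np.all(np.isfinite(s2)):
        raise ValueError("all variances must be finite and non-negative")
    if d <= 0:
        raise ValueError(f"residual degrees of freedom must be positive, got {d}")
    pos = s2[s2 > 0]
    if pos.size < 2:
        raise ValueError(
            "prior estimation needs at least 2 genes with positive residual variance"
        )
    e = np.log(pos) - special.digamma(d / 2.0) + np.log(d / 2.0)
    ebar = float(np.mean(e))
    v = float(np.var(e, ddof=1)) - float(special.polygamma(1, d / 2.0))
    if v > 0:
        d0 = 2.0 * trigamma_inverse(v)
        s0_sq = float(np.exp(ebar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # no excess dispersion: variances look identical up to chi-square
        # sampling noise, so the prior is a point mass at the mean variance
        d0 = np.inf
        s0_sq = float(np.mean(s2))
    return float(d0), s0_sq


def moderated_t_pvalues(
    beta_hat: np.ndarray,
    se_tilde: np.ndarray,
    f_star: float,
    gene_ids: tuple[str, ...] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Moderated t-statistics and two-sided raw p-values.

    t_mod = beta_hat / se_tilde is referred to a t-distribution with
    ``f_star`` degrees of freedom (standard normal when f_star = inf).
    """
    beta_hat = np.asarray(beta_hat, dtype=float)
    se_tilde = np.asarray(se_tilde, dtype=float)
    if np.any(se_tilde <= 0):
        j = int(np.argmax(se_tilde <= 0))
        name = gene_ids[j] if gene_ids else f"index {j}"
        raise ValueError(f"zero shrunken standard error for gene {name}")
    t_mod = beta_hat / se_tilde
    if np.isinf(f_star):
        p_raw = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p_raw = 2.0 * stats.t.sf(np.abs(t_mod), df=f_star)
    return t_mod, np.minimum(p_raw, 1.0)


def fit_two_group(
    expr: ExpressionMatrix,
    groups: GroupAssignment,
    prior_df: float | None = None,
) -> ModeratedFit:
    """Fit the moderated two-group model to every gene.

    Parameters
    ----------
    expr : log-scale expression matrix, genes x samples.
    groups : per-sample group labels (1 = reference, 2 = comparison).
    prior_df : optional override for the prior degrees of freedom d0.
        ``prior_df=0`` disables shrinkage entirely and reproduces the
        classical pooled two-sample t-test; ``None`` (default) estimates
        d0 from the data.

    Returns
    -------
    ModeratedFit with per-gene log fold changes mean(group 2) -
    mean(group 1), shrunken standard errors, moderated t and raw
    p-values.
    """
    if len(groups.labels) != expr.n_samples:
        raise ValueError(
            f"{len(groups.labels)} group labels for {expr.n_samples} samples"
        )
    if expr.n_genes < 2:
        raise ValueError("prior estimation requires at least 2 genes")
    n1, n2 = groups.n1, groups.n2
    d = float(n1 + n2 - 2)
    x1 = expr.values[:, groups.labels == 1]
    x2 = expr.values[:, groups.labels == 2]
    beta_hat = x2.mean(axis=1) - x1.mean(axis=1)
    # pooled within-group variance on d degrees of freedom
    ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x2 - x2.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / d

    if prior_df is None:
        d0, s0_sq = estimate_prior(s2, d)
    else:
        if prior_df < 0:
            raise ValueError(f"prior_df must be non-negative, got {prior_df}")
        d0 = float(prior_df)
        # prior variance only enters through d0 * s0_sq; any finite value
        # works at d0 = 0, and the estimated one is used otherwise
        s0_sq = estimate_prior(s2, d)[1] if d0 > 0 else 1.0

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
    if d0 == 0 and np.any(s2 == 0):
        j = int(np.argmax(s2 == 0))
        raise ValueError(
            f"gene {expr.gene_ids[j]!r} has zero residual variance and "
            "shrinkage is disabled (d0 = 0); its standard error is undefined"
        )
    unscaled_sd = float(np.sqrt(1.0 / n1 + 1.0 / n2))
    se_tilde = np.sqrt(s2_post) * unscaled_sd
    f_star = d0 + d
    t_mod, p_raw = moderated_t_pvalues(beta_hat, se_tilde, f_star, expr.gene_ids)
    return ModeratedFit(
        beta_hat=beta_hat,
        s2=s2,
        d=d,
        d0=d0,
        s0_sq=s0_sq,
        s2_post=s2_post,
        unscaled_sd=unscaled_sd,
        se_tilde=se_tilde,
        f_star=float(f_star),
        t_mod=t_mod,
        p_raw=p_raw,
        gene_ids=expr.gene_ids,
    )
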