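"""Three-class conditionally Gaussian model over each section.

Each pixel of a section is explained by one of three models: foreground
tissue (mean = the slice's predicted contrast image), artifact (tears,
folds; scalar mean ``mu_A``) or background (scalar mean ``mu_B``), each
with its own Gaussian noise scale.  The E-step produces a per-pixel field
of posterior weights; the M-step updates the nuisance means (and
optionally the sigmas); the weighted least-squares cost is the surrogate
minimized by the geometric and contrast blocks of the registration, which
makes the whole alternation a generalized EM with monotone likelihood.

Orientation: the "observation" entering the Gaussians is the deformed,
projected template (template-intensity units); the class-1 mean is the
contrast predicted from the histology section.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.special import logsumexp

from .grids_io import SliceImage

logger = logging.getLogger(__name__)

__all__ = [
    "MixtureParams",
    "class_means",
    "e_step",
    "m_step_nuisance",
    "weighted_cost",
    "negative_log_likelihood",
]


@dataclasses.dataclass
class MixtureParams:
    """Nuisance parameters of the tissue/artifact/background mixture."""

    mu_A: float
    mu_B: float
    sigma: np.ndarray  # (3,) noise scales, > 0
    priors: np.ndarray = None  # (3,) simplex; uniform by default

    def __post_init__(self):
        self.sigma = np.asarray(self.sigma, dtype=float).reshape(3)
        if np.any(self.sigma <= 0):
            raise ValueError("all sigma_k must be > 0")
        if self.priors is None:
            self.priors = np.full(3, 1.0 / 3.0)
        self.priors = np.asarray(self.priors, dtype=float).reshape(3)
        if np.any(self.priors < 0) or abs(self.priors.sum() - 1.0) > 1e-9:
            raise ValueError("priors must lie on the simplex")


def class_means(predicted: SliceImage, params: MixtureParams):
    """Per-class mean images: (J_alpha, mu_A * 1, mu_B * 1) on one lattice."""
    mu1 = predicted.data
    mu2 = np.full_like(mu1, params.mu_A)
    mu3 = np.full_like(mu1, params.mu_B)
    return mu1, mu2, mu3


def _sq_residuals(observed, means):
    """Squared residual per class, summed over channels; obs (*lat, r)."""
    return [np.sum((m - observed) ** 2, axis=-1) for m in means]


def e_step(observed, means, params: MixtureParams):
    """Posterior class weights per pixel (log-sum-exp stabilized).

    ``observed`` is the deformed projected template on the slice lattice,
    shape (*lattice, r); ``means`` the triple from :func:`class_means`.
    Returns weights of shape (*lattice, 3) summing to 1 per pixel.
    """
    observed = np.asarray(observed, dtype=float)
    if not np.all(np.isfinite(observed)):
        raise ValueError("observation contains non-finite values")
    r = observed.shape[-1]
    sq = _sq_residuals(observed, means)
    logp = np.stack(
        [
            np.log(params.priors[k])
            - r * np.log(params.sigma[k])
            - sq[k] / (2.0 * params.sigma[k] ** 2)
            for k in range(3)
        ],
        axis=-1,
    )
    logz = logsumexp(logp, axis=-1, keepdims=True)
    return np.exp(logp - logz)


def m_step_nuisance(observed, weights, params: MixtureParams, update_sigma=False,
                    update_priors=False):
    """Closed-form M-step for the nuisance parameters.

    mu_A / mu_B become the weight-averaged observation of their class;
    when a class has zero total weight its previous value is retained.
    Optional sigma updates set sigma_k^2 to the weighted mean squared
    residual (per channel) of class k; optional prior updates set the
    priors to the mean weight per class.
    """
    observed = np.asarray(observed, dtype=float)
    obs_mean = observed.mean(axis=-1)  # scalar classes share one mean per pixel
    new = dataclasses.replace(params)
    mus = [None, params.mu_A, params.mu_B]
    for k in (1, 2):
        wk = weights[..., k]
        tot = wk.sum()
        if tot <= 0:
            logger.warning("class %d has zero total weight; retaining mean", k + 1)
            continue
        mus[k] = float((wk * obs_mean).sum() / tot)
    new.mu_A, new.mu_B = mus[1], mus[2]
    if update_sigma:
        r = observed.shape[-1]
        means = (None, np.full_like(observed, new.mu_A), np.full_like(observed, new.mu_B))
        sig = new.sigma.copy()
        for k in range(3):
            wk = weights[..., k]
            tot = wk.sum()
            if tot <= 0:
                continue
            if k == 0:
                continue  # class-1 mean is the predicted image, updated elsewhere
            sq = np.sum((means[k] - observed) ** 2, axis=-1)
            sig[k] = max(np.sqrt((wk * sq).sum() / (r * tot)), 1e-6)
        new.sigma = sig
    if update_priors:
        p = weights.reshape(-1, 3).mean(axis=0)
        new.priors = p / p.sum()
    return new


def weighted_cost(observed, means, weights, params: MixtureParams) -> float:
    """EM surrogate: sum_k 1/(2 sigma_k^2) sum_y pi_k(y) |mu_k(y) - obs(y)|^2."""
    observed = np.asarray(observed, dtype=float)
    sq = _sq_residuals(observed, means)
    total = 0.0
    for k in range(3):
        total += np.sum(weights[..., k] * sq[k]) / (2.0 * params.sigma[k] ** 2)
    return float(total)


def negative_log_likelihood(observed, means, params: MixtureParams) -> float:
    """Marginal negative log-likelihood of the three-class model.

    This is the quantity the GEM alternation monotonically decreases;
    the registration drivers record it (plus the deformation penalties)
    as the energy trace.  Constant terms in (2 pi) are dropped.
    """
    observed = np.asarray(observed, dtype=float)
    r = observed.shape[-1]
    sq = _sq_residuals(observed, means)
    logp = np.stack(
        [
            np.log(params.priors[k])
            - r * np.log(params.sigma[k])
            - sq[k] / (2.0 * params.sigma[k] ** 2)
            for k in range(3)
        ],
        axis=-1,
    )
    return float(-np.sum(logsumexp(logp, axis=-1)))
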