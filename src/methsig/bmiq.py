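"""Beta-mixture quantile normalisation of type-II probe betas (BMIQ-style).

The two 450K assay chemistries produce systematically different beta
distributions: type-II betas are compressed toward 0.5 relative to type-I
betas measured in the same sample. Normalisation proceeds per sample:

1. fit a three-state (unmethylated / hemimethylated / methylated) beta
   mixture by EM separately to the type-I and the type-II betas;
2. map every type-II beta through the composition of the fitted mixture
   CDFs, b -> F_I^{-1}(F_II(b)), so the type-II distribution is dilated
   onto the type-I mixture state by state;
3. return type-I betas unchanged.

The map is strictly monotone on (0, 1) (mixture CDFs are strictly
increasing), so within-sample rank order of type-II betas is preserved, and
it is the identity in the limit where the two fitted mixtures coincide.

EM uses weighted method-of-moments updates for the beta parameters of each
component, a fixed deterministic initialisation (component means 0.1 / 0.5 /
0.85), a tolerance of 1e-5 on the mean per-observation log-likelihood
change, and at most 500 iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

__all__ = ["BetaMixture", "fit_beta_mixture", "bmiq_normalize", "bmiq_normalize_matrix"]

_EPS = 1e-4
_N_STATES = 3


@dataclass
class BetaMixture:
    """A K-component beta mixture: weights w_k and shape pairs (a_k, b_k)."""

    weights: np.ndarray
    a: np.ndarray
    b: np.ndarray
    n_iter: int = 0
    converged: bool = True
    log_likelihood: float = np.nan

    def pdf(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(x, float), _EPS, 1 - _EPS)
        comp = np.stack(
            [
                np.exp(
                    (a - 1) * np.log(x)
                    + (b - 1) * np.log1p(-x)
                    - special.betaln(a, b)
                )
                for a, b in zip(self.a, self.b)
            ]
        )
        return np.tensordot(self.weights, comp, axes=1)

    def cdf(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(x, float), 0.0, 1.0)
        comp = np.stack([special.betainc(a, b, x) for a, b in zip(self.a, self.b)])
        return np.tensordot(self.weights, comp, axes=1)

    def responsibilities(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(x, float), _EPS, 1 - _EPS)
        logp = np.stack(
            [
                np.log(w + 1e-300)
                + (a - 1) * np.log(x)
                + (b - 1) * np.log1p(-x)
                - special.betaln(a, b)
                for w, a, b in zip(self.weights, self.a, self.b)
            ]
        )
        logp -= logp.max(axis=0, keepdims=True)
        p = np.exp(logp)
        return p / p.sum(axis=0, keepdims=True)

    def states(self, x: np.ndarray) -> np.ndarray:
        """Posterior-argmax state per value; ties resolve to the lower state."""
        r = self.responsibilities(x)
        # argmax picks the first (lowest-index) maximum, which is the lower state
        return np.argmax(r, axis=0)


def _mom_params(mean: float, var: float) -> tuple[float, float]:
    """Beta shape parameters from a (mean, variance) pair, guarded."""
    mean = float(np.clip(mean, 1e-3, 1 - 1e-3))
    var = float(np.clip(var, 1e-6, mean * (1 - mean) * 0.999))
    phi = mean * (1 - mean) / var - 1.0
    phi = float(np.clip(phi, 0.05, 1e5))
    return mean * phi, (1 - mean) * phi


def fit_beta_mixture(
    betas: np.ndarray,
    n_states: int = _N_STATES,
    tol: float = 1e-5,
    max_iter: int = 500,
    init_means: tuple[float, ...] = (0.1, 0.5, 0.85),
) -> BetaMixture:
    """Fit a beta mixture by EM with weighted method-of-moments M-steps.

    Deterministic: initialisation is fixed (no RNG). Raises ``RuntimeError``
    with diagnostics if EM has not converged after ``max_iter`` iterations,
    and ``ValueError`` if a fitted state ends up effectively empty.
    """
    x = np.clip(np.asarray(betas, float), _EPS, 1 - _EPS)
    if x.size < 10 * n_states:
        raise ValueError(f"too few betas ({x.size}) to fit a {n_states}-state mixture")
    means = np.asarray(init_means[:n_states], float)
    variances = np.full(n_states, 0.01)
    weights = np.full(n_states, 1.0 / n_states)
    a = np.empty(n_states)
    b = np.empty(n_states)
    for k in range(n_states):
        a[k], b[k] = _mom_params(means[k], variances[k])
    mix = BetaMixture(weights, a, b)
    prev_ll = -np.inf
    for it in range(1, max_iter + 1):
        r = mix.responsibilities(x)  # K x n
        nk = r.sum(axis=1)
        if (nk < 2.0).any():
            raise ValueError(
                f"mixture state collapsed (effective counts {nk.round(2)})"
            )
        weights = nk / x.size
        mu = (r @ x) / nk
        var = (r @ (x * x)) / nk - mu**2
        for k in range(n_states):
            a[k], b[k] = _mom_params(mu[k], var[k])
        order = np.argsort(mu)  # keep states ordered U < H < M
        mix = BetaMixture(weights[order], a[order], b[order])
        ll = float(np.sum(np.log(mix.pdf(x) + 1e-300)))
        # tolerance applies to the mean per-observation log-likelihood change
        if it > 1 and abs(ll - prev_ll) < tol * x.size:
            mix.n_iter = it
            mix.converged = True
            mix.log_likelihood = ll
            return mix
        prev_ll = ll
    raise RuntimeError(
        "beta-mixture EM did not converge after "
        f"{max_iter} iterations (last log-likelihood {prev_ll:.4f}, "
        f"weights {np.round(weights, 3)})"
    )


def _quantile_map(mix_from: BetaMixture, mix_to: BetaMixture, x: np.ndarray) -> np.ndarray:
    """Monotone map F_to^{-1}(F_from(x)) via a dense grid inversion."""
    grid = np.linspace(_EPS, 1 - _EPS, 4001)
    cdf_to = mix_to.cdf(grid)
    # strictly increasing by construction; enforce against float round-off
    cdf_to = np.maximum.accumulate(cdf_to)
    u = mix_from.cdf(np.clip(x, _EPS, 1 - _EPS))
    return np.interp(u, cdf_to, grid)


def bmiq_normalize(
    betas: np.ndarray,
    assay_type: np.ndarray,
    tol: float = 1e-5,
    max_iter: int = 500,
) -> tuple[np.ndarray, dict]:
    """Normalise one sample's type-II betas onto its type-I beta mixture.

    Parameters
    ----------
    betas
        All betas of one sample.
    assay_type
        Matching array of ``"I"`` / ``"II"`` labels.

    Returns
    -------
    (normalized, qc)
        ``normalized`` has type-I entries unchanged and type-II entries
        mapped; ``qc`` records the fitted mixtures and iteration counts.
    """
    betas = np.asarray(betas, float)
    assay_type = np.asarray(assay_type)
    t1 = assay_type == "I"
    t2 = assay_type == "II"
    if not t1.any() or not t2.any():
        raise ValueError("both probe types must be present")
    mix1 = fit_beta_mixture(betas[t1], tol=tol, max_iter=max_iter)
    mix2 = fit_beta_mixture(betas[t2], tol=tol, max_iter=max_iter)
    out = betas.copy()
    out[t2] = np.clip(_quantile_map(mix2, mix1, betas[t2]), 0.0, 1.0)
    qc = {
        "type1_mixture": mix1,
        "type2_mixture": mix2,
        "n_type1": int(t1.sum()),
        "n_type2": int(t2.sum()),
        "em_iterations": (mix1.n_iter, mix2.n_iter),
    }
    return out, qc


def bmiq_normalize_matrix(
    betas: pd.DataFrame, assay_type: pd.Series, tol: float = 1e-5, max_iter: int = 500
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply :func:`bmiq_normalize` column-wise (per sample).

    ``assay_type`` is indexed by probe id. Returns the normalised matrix and
    a per-sample QC frame (EM iterations, state weights).
    """
    at = assay_type.loc[betas.index].to_numpy()
    cols = {}
    qc_rows = []
    for sample in betas.columns:
        norm, qc = bmiq_normalize(betas[sample].to_numpy(), at, tol=tol, max_iter=max_iter)
        cols[sample] = norm
        m1, m2 = qc["type1_mixture"], qc["type2_mixture"]
        qc_rows.append(
            {
                "sample": sample,
                "em_iter_type1": m1.n_iter,
                "em_iter_type2": m2.n_iter,
                "w_unmeth_type1": m1.weights[0],
                "w_meth_type1": m1.weights[-1],
                "w_unmeth_type2": m2.weights[0],
                "w_meth_type2": m2.weights[-1],
            }
        )
    out = pd.DataFrame(cols, index=betas.index)[betas.columns]
    return out, pd.DataFrame(qc_rows)
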