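"""Wilson normalization, second moments, posterior intensity handling and
outlier rejection.

Normalized intensities are z = I / (eps_sym * eps_tncs * A * Sigma(s))
where Sigma(s) is an equal-count binned mean-intensity curve and A is an
anisotropic scale factor. Clean acentric z is unit-mean exponential,
centric z a scaled chi-squared with one degree of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "Binning",
    "NormalizationState",
    "make_binning",
    "estimate_sigma_curve",
    "second_moments",
    "reject_outliers",
    "detect_french_wilson",
    "french_wilson_posterior",
]


@dataclass(frozen=True)
class Binning:
    """Equal-count resolution bins in s^2 (1/A^2)."""

    edges: np.ndarray            # len nbins+1, ascending s^2
    assignments: np.ndarray      # bin index per reflection

    @property
    def nbins(self) -> int:
        return len(self.edges) - 1

    def counts(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.nbins)


def make_binning(s_squared: np.ndarray, nbins: int = 20, min_per_bin: int = 50) -> Binning:
    """Equal-count bins; the bin count is reduced so no bin falls below
    ``min_per_bin`` reflections."""
    s2 = np.asarray(s_squared, dtype=float)
    n = len(s2)
    if n == 0:
        raise ValueError("no reflections to bin")
    nbins = max(1, min(nbins, n // min_per_bin))
    qs = np.quantile(s2, np.linspace(0, 1, nbins + 1))
    qs[0] -= 1e-12
    qs[-1] += 1e-12
    # collapse duplicate edges (heavily tied s^2 values)
    qs = np.unique(qs)
    assignments = np.clip(np.searchsorted(qs, s2, side="right") - 1, 0, len(qs) - 2)
    return Binning(edges=qs, assignments=assignments)


@dataclass
class NormalizationState:
    binning: Binning
    Sigma: np.ndarray                 # per-bin mean corrected intensity
    eps_sym: np.ndarray
    eps_tncs: np.ndarray
    aniso: np.ndarray
    z: np.ndarray
    mask: np.ndarray                  # True = kept
    n_iter: int = 0
    converged: bool = True
    centric: np.ndarray | None = field(default=None, repr=False)

    def expected_intensity(self) -> np.ndarray:
        """mu(h) = eps_sym * eps_tncs * A * Sigma(s) on the input scale."""
        return (
            self.eps_sym
            * self.eps_tncs
            * self.aniso
            * self.Sigma[self.binning.assignments]
        )


def estimate_sigma_curve(
    dataset,
    binning: Binning,
    eps_sym: np.ndarray | None = None,
    eps_tncs: np.ndarray | None = None,
    aniso: np.ndarray | None = None,
    centric: np.ndarray | None = None,
    p_cut: float = 1e-6,
    tol: float = 1e-6,
    max_iter: int = 20,
) -> NormalizationState:
    """Fixed-point estimate of the mean-intensity curve Sigma(s), jointly
    with Wilson-tail outlier masking."""
    n = dataset.n
    ones = np.ones(n)
    eps_sym = ones if eps_sym is None else np.asarray(eps_sym, float)
    eps_tncs = ones if eps_tncs is None else np.asarray(eps_tncs, float)
    aniso = ones if aniso is None else np.asarray(aniso, float)
    if np.any(eps_sym <= 0) or np.any(eps_tncs <= 0) or np.any(aniso <= 0):
        raise ValueError("expected-intensity factors must be positive")
    if centric is None:
        centric = dataset.centric()

    corrected = dataset.I / (eps_sym * eps_tncs * aniso)
    assign = binning.assignments
    nb = binning.nbins
    mask = np.ones(n, dtype=bool)
    Sigma = np.ones(nb)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        sums = np.bincount(assign[mask], weights=corrected[mask], minlength=nb)
        counts = np.bincount(assign[mask], minlength=nb).astype(float)
        # empty bin: borrow the nearest populated neighbour
        new = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        if np.any(np.isnan(new)):
            good = np.flatnonzero(~np.isnan(new))
            if len(good) == 0:
                raise ValueError("all bins empty")
            for b in np.flatnonzero(np.isnan(new)):
                new[b] = new[good[np.argmin(np.abs(good - b))]]
        new = np.maximum(new, 1e-300)
        delta = np.max(np.abs(new - Sigma) / new)
        Sigma = new
        z = corrected / Sigma[assign]
        mask = _outlier_mask(z, centric, p_cut)
        if delta < tol:
            converged = True
            break
    return NormalizationState(
        binning=binning,
        Sigma=Sigma,
        eps_sym=eps_sym,
        eps_tncs=eps_tncs,
        aniso=aniso,
        z=z,
        mask=mask,
        n_iter=it,
        converged=converged,
        centric=centric,
    )


def _outlier_mask(z: np.ndarray, centric: np.ndarray, p_cut: float) -> np.ndarray:
    acen_cut = -np.log(p_cut)
    cen_cut = stats.norm.ppf(1 - p_cut / 2.0) ** 2
    cut = np.where(centric, cen_cut, acen_cut)
    return z <= cut


def reject_outliers(state: NormalizationState, centric_flags=None, p_cut: float = 1e-6):
    """Extreme-tail rejection mask under the Wilson null: acentric cut at
    -ln(p), centric at the squared two-sided normal quantile."""
    if not 0 < p_cut < 0.1:
        raise ValueError("p_cut must lie in (0, 0.1)")
    centric = state.centric if centric_flags is None else np.asarray(centric_flags, bool)
    return _outlier_mask(state.z, centric, p_cut)


def second_moments(state: NormalizationState, centric_flags=None) -> dict:
    """Count-weighted second moments <z^2>/<z>^2 with jackknife-over-bins
    standard errors, per centricity class.

    Classes with fewer than 2 populated bins (>=10 reflections each) are
    reported as absent (value None).
    """
    centric = state.centric if centric_flags is None else np.asarray(centric_flags, bool)
    out = {}
    for name, sel_class in (("acentric", ~centric), ("centric", centric)):
        sel = sel_class & state.mask
        out[name] = _class_moment(state.z[sel], state.binning.assignments[sel], state.binning.nbins)
    return out


def _class_moment(z: np.ndarray, assign: np.ndarray, nb: int) -> dict:
    counts = np.bincount(assign, minlength=nb)
    good = counts >= 10
    if good.sum() < 2:
        return {"m2": None, "se": None, "n": int(len(z))}
    s1 = np.bincount(assign, weights=z, minlength=nb)
    s2 = np.bincount(assign, weights=z * z, minlength=nb)
    c = counts[good].astype(float)
    s1, s2 = s1[good], s2[good]
    m2_bins = (s2 / c) / (s1 / c) ** 2

    def weighted(cs, m2s):
        return float(np.sum(cs * m2s) / np.sum(cs))

    m2 = weighted(c, m2_bins)
    # jackknife over bins
    k = len(c)
    loo = np.array(
        [weighted(np.delete(c, i), np.delete(m2_bins, i)) for i in range(k)]
    )
    se = float(np.sqrt((k - 1) / k * np.sum((loo - loo.mean()) ** 2)))
    return {"m2": m2, "se": se, "n": int(np.sum(c))}


def detect_french_wilson(dataset, state: NormalizationState | None = None) -> dict:
    """Heuristic screen for data already pushed through a Bayesian
    posterior-intensity treatment: no negative intensities at all AND a
    depleted low tail of the acentric z distribution."""
    frac_negative = float(np.mean(dataset.I < 0))
    if state is None:
        binning = make_binning(dataset.s_squared())
        state = estimate_sigma_curve(dataset, binning, eps_sym=dataset.epsilon())
    centric = state.centric
    z_acen = state.z[~centric] if centric is not None else state.z
    expect = 1.0 - np.exp(-0.05)  # P(z < 0.05) for unit exponential
    frac_low = float(np.mean(z_acen < 0.05)) if len(z_acen) else 0.0
    deficit = 1.0 - frac_low / expect
    suspected = frac_negative == 0.0 and deficit > 0.5
    return {
        "suspected": bool(suspected),
        "evidence": {"frac_negative": frac_negative, "low_tail_deficit": deficit},
    }


def french_wilson_posterior(I: float, sigI: float, Sigma: float) -> dict:
    """Posterior moments of the true intensity under an acentric Wilson
    (exponential, mean Sigma) prior and Gaussian measurement likelihood.

    The posterior is a Gaussian with shifted centre mu' = I - sigI^2/Sigma
    truncated to J > 0; intensity moments are closed-form, amplitude
    moments are evaluated by quadrature over the truncated density.
    """
    if sigI <= 0:
        raise ValueError("sigI must be positive")
    if Sigma <= 0:
        raise ValueError("Sigma must be positive")
    mu = I - sigI * sigI / Sigma
    a = -mu / sigI  # lower truncation bound in standard units
    tn = stats.truncnorm(a, np.inf, loc=mu, scale=sigI)
    I_post = float(tn.mean())
    sigI_post = float(tn.std())

    # amplitude moments by Gauss-Legendre over the bulk of the posterior
    hi = mu + 10 * sigI
    nodes, weights = np.polynomial.legendre.leggauss(200)
    j = 0.5 * hi * (nodes + 1.0)
    w = 0.5 * hi * weights
    pdf = tn.pdf(j)
    norm = float(np.sum(w * pdf))
    F_post = float(np.sum(w * np.sqrt(j) * pdf) / norm)
    F2 = float(np.sum(w * j * pdf) / norm)
    sigF_post = float(np.sqrt(max(F2 - F_post**2, 0.0)))
    return {
        "I_post": I_post,
        "sigI_post": sigI_post,
        "F_post": F_post,
        "sigF_post": sigF_post,
    }
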