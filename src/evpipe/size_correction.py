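"""Lognormal size-mixture decomposition of single-positive radius histograms.

Double-positive particles provide the vesicle size reference (lognormal,
median around 60 nm of the radius-of-gyration feature); antibody-only
controls provide the aggregate reference (median around 20 nm).  A
single-positive radius histogram is then expressed as a weighted sum of the
two reference densities; the EV weight gives the purity of the class, and
corrected phenotype counts follow by down-weighting the single positives.

Fitting is least squares on the probability-density histogram (50 nm bins by
default); the direct MLE of the lognormal parameters is reported alongside as
a cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, minimize_scalar
from scipy.special import ndtr

from evpipe.phenotyping import PhenotypeSummary, PHENOTYPES

DEFAULT_BIN_WIDTH_NM = 50.0
HIST_UPPER_QUANTILE = 0.995


class DegenerateFitError(ValueError):
    pass


@dataclass
class LognormalComponent:
    """One lognormal density: ``mu`` is the log-nm location, ``sigma`` the log-scale."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")

    @property
    def median(self) -> float:
        return float(np.exp(self.mu))

    def pdf(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        out = np.zeros_like(r)
        pos = r > 0
        z = (np.log(r[pos]) - self.mu) / self.sigma
        out[pos] = np.exp(-0.5 * z**2) / (r[pos] * self.sigma * np.sqrt(2 * np.pi))
        return out

    def cdf(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        out = np.zeros_like(r)
        pos = r > 0
        out[pos] = ndtr((np.log(r[pos]) - self.mu) / self.sigma)
        return out

    def bin_density(self, edges: np.ndarray) -> np.ndarray:
        """Bin-averaged density: (CDF(hi) - CDF(lo)) / width per bin.

        This, not the pdf at bin centres, is what a probability-density
        histogram estimates; the distinction matters whenever a component is
        narrow relative to the bin width.
        """
        c = self.cdf(edges)
        return np.diff(c) / np.diff(edges)


@dataclass
class FitDiagnostics:
    rss: float
    r_squared: float
    mle_mu: float
    mle_sigma: float
    n: int


@dataclass
class MixtureDecomposition:
    ev_component: LognormalComponent
    ab_component: LognormalComponent
    w_ev: float
    r_squared: float
    n: int
    ill_conditioned: bool = False
    bin_edges: np.ndarray = field(default=None, repr=False)
    density: np.ndarray = field(default=None, repr=False)

    @property
    def w_ab(self) -> float:
        return 1.0 - self.w_ev

    # with unit-weight densities the areas under the weighted curves
    # are the weights themselves
    @property
    def area_ev(self) -> float:
        return self.w_ev

    @property
    def area_ab(self) -> float:
        return self.w_ab


@dataclass
class CorrectedSummary:
    counts: dict[str, float]
    fractions: dict[str, float]
    correction_method: str

    @property
    def dp_fraction(self) -> float:
        return self.fractions["double_positive"]


def radius_histogram(
    radii: np.ndarray,
    bin_width: float = DEFAULT_BIN_WIDTH_NM,
    upper_quantile: float = HIST_UPPER_QUANTILE,
) -> tuple[np.ndarray, np.ndarray]:
    """Probability-density histogram with uniform bins on [0, q-th percentile].

    Returns (bin_edges, density). Bin range is clipped at the upper quantile
    so a handful of outliers cannot dominate the least-squares objective.
    """
    radii = np.asarray(radii, dtype=float)
    if len(radii) == 0:
        raise ValueError("no radii")
    if (radii <= 0).any():
        raise ValueError("radii must be > 0")
    hi = float(np.quantile(radii, upper_quantile))
    n_bins = max(2, int(np.ceil(hi / bin_width)))
    edges = np.arange(n_bins + 1, dtype=float) * bin_width
    clipped = radii[radii <= edges[-1]]
    density, _ = np.histogram(clipped, bins=edges, density=True)
    return edges, density


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")


def fit_lognormal(
    radii: np.ndarray, bin_width: float = DEFAULT_BIN_WIDTH_NM
) -> tuple[LognormalComponent, FitDiagnostics]:
    """Least-squares lognormal fit to the radius probability-density histogram.

    The MLE (mean/SD of log radii) seeds the optimizer and is returned in the
    diagnostics as an independent cross-check.  Raises
    :class:`DegenerateFitError` when the radii carry no spread.
    """
    radii = np.asarray(radii, dtype=float)
    if len(radii) < 2 or np.ptp(radii) == 0:
        raise DegenerateFitError("radii are constant; lognormal fit undefined")
    log_r = np.log(radii)
    mle_mu, mle_sigma = float(log_r.mean()), float(log_r.std(ddof=0))
    if mle_sigma == 0:
        raise DegenerateFitError("zero spread in log radii")

    edges, density = radius_histogram(radii, bin_width)

    if int((density > 0).sum()) >= 4:
        def model(_, mu, sigma):
            return LognormalComponent(mu, abs(sigma) + 1e-12).bin_density(edges)

        popt, _ = curve_fit(
            model, edges[:-1], density, p0=[mle_mu, mle_sigma], maxfev=20000
        )
        comp = LognormalComponent(float(popt[0]), float(abs(popt[1])))
    else:
        # too few occupied bins to constrain a 2-parameter histogram fit
        # (e.g. aggregate radii inside a single 50 nm bin): fall back to MLE
        comp = LognormalComponent(mle_mu, mle_sigma)
    yhat = comp.bin_density(edges)
    diag = FitDiagnostics(
        rss=float(((density - yhat) ** 2).sum()),
        r_squared=_r_squared(density, yhat),
        mle_mu=mle_mu,
        mle_sigma=mle_sigma,
        n=len(radii),
    )
    return comp, diag


def decompose_single_positive(
    sp_radii: np.ndarray,
    ev_ref: LognormalComponent,
    ab_ref: LognormalComponent,
    bin_width: float = DEFAULT_BIN_WIDTH_NM,
    fix_shapes: bool = True,
) -> MixtureDecomposition:
    """Fit the EV mixture weight of a single-positive radius histogram.

    With ``fix_shapes`` (default) the two component shapes stay frozen at the
    reference fits and only the weight ``w_ev`` is estimated, by bounded
    least squares of ``w*pdf_ev + (1-w)*pdf_ab`` against the histogram
    density.  ``fix_shapes=False`` refits all five mixture parameters.

    Emits an ill-conditioned warning when the reference medians are within
    10% of each other.
    """
    sp_radii = np.asarray(sp_radii, dtype=float)
    if len(sp_radii) == 0:
        raise ValueError("sp_radii is empty")
    ill = abs(ev_ref.median - ab_ref.median) < 0.10 * max(
        ev_ref.median, ab_ref.median
    )
    if ill:
        warnings.warn(
            "reference components nearly identical; weight fit is ill-conditioned",
            RuntimeWarning,
        )
    edges, density = radius_histogram(sp_radii, bin_width)

    if fix_shapes:
        f_ev = ev_ref.bin_density(edges)
        f_ab = ab_ref.bin_density(edges)

        def sse(w: float) -> float:
            return float(((density - (w * f_ev + (1 - w) * f_ab)) ** 2).sum())

        res = minimize_scalar(sse, bounds=(0.0, 1.0), method="bounded",
                              options={"xatol": 1e-6})
        w_ev = float(res.x)
        ev_c, ab_c = ev_ref, ab_ref
    else:
        if int((density > 0).sum()) < 6:
            raise ValueError(
                "too few occupied bins for a free 5-parameter mixture fit; "
                "use fix_shapes=True or a smaller bin_width"
            )

        def model(_, w, mu1, s1, mu2, s2):
            w = np.clip(w, 0, 1)
            return (
                w * LognormalComponent(mu1, abs(s1) + 1e-12).bin_density(edges)
                + (1 - w) * LognormalComponent(mu2, abs(s2) + 1e-12).bin_density(edges)
            )

        p0 = [0.5, ev_ref.mu, ev_ref.sigma, ab_ref.mu, ab_ref.sigma]
        popt, _ = curve_fit(model, edges[:-1], density, p0=p0, maxfev=50000)
        w_ev = float(np.clip(popt[0], 0, 1))
        ev_c = LognormalComponent(float(popt[1]), float(abs(popt[2])))
        ab_c = LognormalComponent(float(popt[3]), float(abs(popt[4])))

    yhat = w_ev * ev_c.bin_density(edges) + (1 - w_ev) * ab_c.bin_density(edges)
    return MixtureDecomposition(
        ev_component=ev_c,
        ab_component=ab_c,
        w_ev=w_ev,
        r_squared=_r_squared(density, yhat),
        n=len(sp_radii),
        ill_conditioned=ill,
        bin_edges=edges,
        density=density,
    )


def correct_summary(
    raw: PhenotypeSummary,
    decomp_cd9: MixtureDecomposition,
    decomp_cd81: MixtureDecomposition,
) -> CorrectedSummary:
    """Down-weight single-positive counts by their EV purity and renormalize.

    Double-positive counts are left untouched; corrected single-positive
    counts are ``raw count x w_ev`` per class, so the double-positive
    fraction can only stay equal or grow.
    """
    counts = {
        "CD81_only": raw.counts["CD81_only"] * decomp_cd81.w_ev,
        "CD9_only": raw.counts["CD9_only"] * decomp_cd9.w_ev,
        "double_positive": float(raw.counts["double_positive"]),
    }
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no particles left after correction")
    fractions = {p: counts[p] / total for p in PHENOTYPES}
    return CorrectedSummary(counts=counts, fractions=fractions, correction_method="size_fit")
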