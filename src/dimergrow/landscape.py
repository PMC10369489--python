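"""Growth landscape over the (theta_pol, phi_pol) plane.

Scanning the two polymerization angles on a regular grid (5 degree step by
default) and classifying each sphere-model chain yields a two-dimensional
growth landscape: a limited region at low theta, an unlimited region at
high theta, and a transition between them.  The transition points -- for
each dihedral column, the largest theta still classified limited -- are
fitted with a three-parameter exponential

    theta*(phi) = a * exp(b * phi) + c

and arbitrary dimers are then classified as limited, uncertain (within a
band around the fitted boundary, where the sphere approximation should not
be trusted and atomic replication is warranted) or unlimited.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import curve_fit

from .spheremodel import classify_sphere_growth

__all__ = [
    "GrowthLandscape",
    "scan_landscape",
    "cached_landscape",
    "fit_boundary",
    "classify_region",
    "ensemble_representative",
    "plot_landscape",
]


@dataclass
class GrowthLandscape:
    """5-degree-grid growth classification with a fitted boundary."""

    thetas: np.ndarray
    phis: np.ndarray
    limited: np.ndarray  # bool, shape (n_theta, n_phi)
    n_monomers: int
    delta: float
    transition: np.ndarray | None = None  # theta* per phi column
    fit_params: tuple[float, float, float] | None = None
    fit_residual_rms: float | None = None
    uncertain_halfwidth: float = 10.0

    def theta_star(self, phi) -> np.ndarray:
        """Fitted boundary theta*(phi)."""
        if self.fit_params is None:
            raise ValueError("boundary not fitted yet; call fit_boundary first")
        a, b, c = self.fit_params
        return a * np.exp(b * np.asarray(phi, dtype=float)) + c

    def smallest_unlimited_theta(self) -> float:
        """Smallest grid theta with at least one unlimited dihedral."""
        rows = ~self.limited
        idx = np.flatnonzero(rows.any(axis=1))
        if len(idx) == 0:
            raise ValueError("no unlimited cell in the landscape")
        return float(self.thetas[idx[0]])

    def to_frame(self):
        """Long-format table (theta, phi, mode) for export."""
        import pandas as pd

        tt, pp = np.meshgrid(self.thetas, self.phis, indexing="ij")
        return pd.DataFrame(
            {
                "theta": tt.ravel(),
                "phi": pp.ravel(),
                "mode": np.where(self.limited.ravel(), "limited", "unlimited"),
            }
        )


def scan_landscape(
    step: float = 5.0, n: int = 32, delta: float = 0.05, fit: bool = True
) -> GrowthLandscape:
    """Classify every (theta, phi) grid cell in [0, 180]^2.

    ``step`` must divide 180.  The scan is deterministic: identical inputs
    produce identical landscapes.  The boundary is fitted unless
    ``fit=False``.
    """
    if step <= 0 or abs(round(180.0 / step) - 180.0 / step) > 1e-9:
        raise ValueError("step must be positive and divide 180 degrees")
    grid = np.arange(0.0, 180.0 + step / 2, step)
    limited = np.empty((len(grid), len(grid)), dtype=bool)
    for i, th in enumerate(grid):
        for j, ph in enumerate(grid):
            cls = classify_sphere_growth(th, ph, n=n, delta=delta)
            limited[i, j] = cls.mode == "limited"
    landscape = GrowthLandscape(
        thetas=grid, phis=grid.copy(), limited=limited, n_monomers=n, delta=delta
    )
    if fit:
        fit_boundary(landscape)
    return landscape


@lru_cache(maxsize=4)
def cached_landscape(
    step: float = 5.0, n: int = 32, delta: float = 0.05
) -> GrowthLandscape:
    """Memoized :func:`scan_landscape` (the scan is deterministic)."""
    return scan_landscape(step=step, n=n, delta=delta)


def _exp_model(x, a, b, c):
    return a * np.exp(b * x) + c


def fit_boundary(
    landscape: GrowthLandscape, transition: np.ndarray | None = None
) -> tuple[float, float, float]:
    """Fit theta*(phi) = a*exp(b*phi) + c through the transition points.

    The transition point of a phi column is the largest theta classified
    limited (the upper limit of limited angle/dihedral combinations);
    explicit transition values may be supplied instead via ``transition``.
    Stores and returns the fitted parameters; the residual RMS is kept on
    the landscape.  A degenerate (constant) transition set yields a flat
    fit with a warning.
    """
    if transition is not None:
        transition = np.asarray(transition, dtype=float)
        if transition.shape != landscape.phis.shape:
            raise ValueError("transition must hold one theta* per phi column")
    else:
        transition = np.empty(len(landscape.phis))
        for j in range(len(landscape.phis)):
            lim = np.flatnonzero(landscape.limited[:, j])
            transition[j] = landscape.thetas[lim[-1]] if len(lim) else np.nan
    valid = ~np.isnan(transition)
    if valid.sum() < 3:
        raise ValueError("need at least 3 transition points to fit a boundary")
    x = landscape.phis[valid]
    y = transition[valid]
    landscape.transition = transition
    if np.ptp(y) < 1e-12:
        warnings.warn(
            "transition points are constant; returning a flat boundary",
            stacklevel=2,
        )
        params = (0.0, 0.0, float(y[0]))
    else:
        p0 = (float(y[0] - y.min()), -0.05, float(y.min()))
        popt, _ = curve_fit(_exp_model, x, y, p0=p0, maxfev=20000)
        params = tuple(float(v) for v in popt)
    landscape.fit_params = params
    resid = y - _exp_model(x, *params)
    landscape.fit_residual_rms = float(np.sqrt(np.mean(resid**2)))
    return params


def classify_region(
    landscape: GrowthLandscape, theta: float, phi: float, band: float | None = None
) -> str:
    """Classify a (theta, phi) point as limited, uncertain or unlimited.

    The point is *uncertain* when theta lies within ``band`` degrees
    (default: the landscape's uncertain half-width, 10 degrees) of the
    fitted boundary theta*(phi); otherwise limited below the boundary and
    unlimited above it.
    """
    if not (0.0 <= theta <= 180.0 and 0.0 <= phi <= 180.0):
        raise ValueError("theta and phi must lie in [0, 180] degrees")
    band = landscape.uncertain_halfwidth if band is None else band
    tstar = float(landscape.theta_star(phi))
    if abs(theta - tstar) <= band:
        return "uncertain"
    return "limited" if theta < tstar else "unlimited"


def ensemble_representative(angles) -> int:
    """Index of the conformation closest to the ensemble-average angles.

    ``angles`` is a sequence of (theta, phi) pairs; the representative (the
    "average conformation") minimizes the Euclidean distance in the angle
    plane to the component-wise mean, ties broken by the lowest index.
    Means are arithmetic: observed angles live well inside [0, 180], so no
    circular statistics are applied.
    """
    arr = np.asarray(list(angles), dtype=float)
    if arr.size == 0:
        raise ValueError("empty angle ensemble")
    arr = arr.reshape(len(arr), -1)
    mean = arr.mean(axis=0)
    dist = np.linalg.norm(arr - mean, axis=1)
    return int(np.argmin(dist))


def plot_landscape(landscape: GrowthLandscape, path=None, ax=None):
    """Render the landscape (limited region, uncertain band, boundary curve)."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    tt, pp = np.meshgrid(landscape.thetas, landscape.phis, indexing="ij")
    ax.pcolormesh(
        pp, tt, landscape.limited.astype(float), cmap="Oranges", shading="nearest",
        alpha=0.8,
    )
    if landscape.transition is not None:
        ax.plot(landscape.phis, landscape.transition, "k.", label="transition")
    if landscape.fit_params is not None:
        xs = np.linspace(landscape.phis[0], landscape.phis[-1], 200)
        ys = landscape.theta_star(xs)
        ax.plot(xs, ys, "k-", label="fitted boundary")
        ax.fill_between(
            xs,
            ys - landscape.uncertain_halfwidth,
            ys + landscape.uncertain_halfwidth,
            color="gold",
            alpha=0.4,
            label="uncertain band",
        )
    ax.set_xlabel(r"$\phi_{pol}$ (deg)")
    ax.set_ylabel(r"$\theta_{pol}$ (deg)")
    ax.set_xlim(0, 180)
    ax.set_ylim(0, 180)
    ax.legend(loc="upper right", fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
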