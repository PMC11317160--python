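"""Pol delta/delta bias and restart-fraction / progression inference.

At a polar replication fork barrier, HR-restarted forks synthesize BOTH
strands with Pol delta, while canonical forks split the work (leading
Pol epsilon / lagging Pol delta). The per-bin delta/delta bias

    b(x) = (U_delta^Watson(x) + U_delta^Crick(x)) / 2

is therefore 0.5 under purely canonical replication and 1.0 where every
cell's fork was restarted. Immediately downstream of the barrier the
bias increment above baseline is a linear read-out of the fraction f of
cells whose arrested fork restarted:

    f = (b_prox - b0) / (ceiling - b0),   anchors b=1 -> 100%, b=0.5 -> 0%.

``b0`` is estimated from an upstream window rather than fixed at 0.5;
observed usage can additionally be calibrated against the baseline
window to undo background ribonucleotide incorporation and residual
library-depth imbalance (see :func:`calibrate_usage`) — on ideal data
everything reduces to the 0.5 / 1.0 anchors and ``f = 2 b - 1``.
Restarted-fork progression is summarized by the half-distance
d_half: the downstream distance at which the bias increment first falls
to half its proximal value — slow restarted forks terminate against the
converging canonical fork closer to the barrier, giving a smaller d_half.

Confidence intervals are moving-block bootstrap percentiles over window
bins (block length = the smoothing window, which sets the serial
correlation scale).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np

from .errors import (
    ComparisonError,
    ParameterError,
    ProgressionUndefinedError,
    WindowError,
)
from .tracks import Track
from .usage import UsageTracks

__all__ = [
    "AnalysisWindows",
    "BaselineEstimate",
    "RestartEstimate",
    "ProgressionEstimate",
    "StrainComparison",
    "delta_delta_bias",
    "bias_to_restart_fraction",
    "UsageCalibration",
    "calibrate_usage",
    "bootstrap_restart_fraction",
    "estimate_background",
    "estimate_baseline",
    "estimate_restart",
    "estimate_progression",
    "compare_strains",
]

#: default analysis windows relative to the barrier (bp)
BASELINE_OFFSETS = (-10_000, -2_000)
PROXIMAL_OFFSETS = (500, 2_500)
DEFAULT_PROGRESSION_RANGE = 20_000
#: default bootstrap settings; block length matches the default smoothing window
DEFAULT_N_BOOT = 1000
DEFAULT_BLOCK_LEN = 5


@dataclass(frozen=True)
class AnalysisWindows:
    """Locus description for restart inference (absolute bp coordinates).

    ``baseline_window`` lies entirely upstream of the barrier (default
    -10 kb..-2 kb: far enough left to escape the ~1 kb resection zone and
    any restarted re-synthesis), ``proximal_window`` immediately
    downstream (default +0.5..+2.5 kb: past the resection-perturbed
    barrier bin, before substantial termination), and
    ``progression_range`` is the maximum downstream extent (bp from the
    barrier) scanned for the half-distance.
    """

    barrier_pos: int
    baseline_window: tuple[int, int]
    proximal_window: tuple[int, int]
    progression_range: int

    def __post_init__(self) -> None:
        b0a, b0b = self.baseline_window
        pa, pb = self.proximal_window
        if not b0a < b0b <= self.barrier_pos:
            raise WindowError(
                f"baseline window {self.baseline_window} must lie upstream of barrier "
                f"{self.barrier_pos}"
            )
        if not self.barrier_pos <= pa < pb:
            raise WindowError(
                f"proximal window {self.proximal_window} must lie downstream of barrier "
                f"{self.barrier_pos}"
            )
        if self.barrier_pos + self.progression_range <= pb:
            raise WindowError(
                f"progression_range {self.progression_range} must extend past the "
                f"proximal window end {pb}"
            )

    @classmethod
    def default(cls, barrier_pos: int) -> "AnalysisWindows":
        return cls(
            barrier_pos=barrier_pos,
            baseline_window=(barrier_pos + BASELINE_OFFSETS[0], barrier_pos + BASELINE_OFFSETS[1]),
            proximal_window=(barrier_pos + PROXIMAL_OFFSETS[0], barrier_pos + PROXIMAL_OFFSETS[1]),
            progression_range=DEFAULT_PROGRESSION_RANGE,
        )


@dataclass
class BaselineEstimate:
    value: float
    ci_low: float
    ci_high: float
    n_bins: int


@dataclass
class RestartEstimate:
    """Restart fraction at the barrier with bootstrap CI."""

    b0: float
    b_prox: float
    f: float
    ci_low: float
    ci_high: float
    windows: AnalysisWindows
    ceiling: float = 1.0
    n_boot: int = DEFAULT_N_BOOT
    seed: int | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["windows"] = asdict(self.windows)
        return d


@dataclass
class ProgressionEstimate:
    """Half-distance summary of restarted-fork progression."""

    delta0: float
    d_half: float
    censored: bool

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class StrainComparison:
    relative_restart: float
    relative_progression: float
    ref_censored: bool = False
    mut_censored: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def delta_delta_bias(usage: UsageTracks) -> Track:
    """Mean Pol delta usage across both strands, per bin.

    Masked wherever either strand's usage is masked. Values lie in [0, 1];
    0.5 is canonical replication, 1.0 fully delta/delta (restarted).
    """
    uw, uc = usage.u_delta_watson, usage.u_delta_crick
    vals = 0.5 * (uw.values + uc.values)
    mask = uw.mask | uc.mask
    return uw.with_values(np.where(mask, 0.0, vals), mask)


def bias_to_restart_fraction(b: float, b0: float, ceiling: float = 1.0) -> float:
    """Map a delta/delta bias value to a restart fraction.

    ``f = (b - b0) / (ceiling - b0)``, clipped to [0, 1]. With the ideal
    anchors (b0=0.5, ceiling=1.0) this is ``f = 2 b - 1``: bias 1.0 means
    100% of forks restarted, bias 0.5 means 0%.
    """
    if not 0.0 <= b0 < 1.0:
        raise ParameterError(f"baseline bias must be in [0, 1), got {b0}")
    if not b0 < ceiling <= 1.0:
        raise ParameterError(f"ceiling must be in (b0, 1], got {ceiling}")
    return float(np.clip((b - b0) / (ceiling - b0), 0.0, 1.0))


def _window_values(bias: Track, window: tuple[int, int], min_bins: int = 5) -> np.ndarray:
    """Ordered unmasked bias values whose bin centers fall in [a, b)."""
    a, b = window
    centers = bias.bin_centers()
    sel = (centers >= a) & (centers < b) & ~bias.mask
    vals = bias.values[sel]
    if vals.size < min_bins:
        raise WindowError(
            f"window {window} has only {vals.size} unmasked bins (need >= {min_bins})"
        )
    return vals


def _block_boot_means(vals: np.ndarray, n_boot: int, block_len: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Moving-block bootstrap means of a serially correlated window."""
    n = vals.size
    ell = min(max(1, block_len), n)
    n_blocks = int(np.ceil(n / ell))
    starts = rng.integers(0, n - ell + 1, size=(n_boot, n_blocks))
    idx = (starts[:, :, None] + np.arange(ell)[None, None, :]).reshape(n_boot, -1)[:, :n]
    return vals[idx].mean(axis=1)


def _solve_calibration(u0, u1):
    """Vectorized (beta, kappa) solve from baseline strand means u0 < u1."""
    u0c = np.clip(u0, 1e-6, 0.5 - 1e-6)
    u1c = np.clip(u1, 0.5 + 1e-6, 1.0 - 1e-6)
    o0 = u0c / (1.0 - u0c)
    o1 = u1c / (1.0 - u1c)
    beta_odds = np.sqrt(o0 / o1)
    beta = np.clip(beta_odds / (1.0 + beta_odds), 0.0, 0.49)
    kappa = np.clip(1.0 / np.sqrt(o0 * o1), 1e-3, 1e3)
    return beta, kappa


def _phi_from_usage(u, beta, kappa):
    """Invert the two-parameter usage distortion (broadcasting)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        g = u * kappa / (1.0 - u + u * kappa)
    return np.clip((g - beta) / (1.0 - 2.0 * beta), 0.0, 1.0)


@dataclass
class UsageCalibration:
    """Baseline-anchored calibration of observed usage to synthesis fractions.

    The observed Pol delta usage on a strand is a two-parameter distortion
    of the true synthesis fraction phi:

        U = g / (g + (1 - g) * kappa),    g = beta + (1 - 2 beta) * phi,

    where ``beta`` is the background incorporation fraction (signal from
    the non-mutated polymerase) and ``kappa`` the residual delta/epsilon
    library depth ratio left over by mean normalization. The baseline
    window — replicated unidirectionally by canonical forks — pins both
    parameters: the leading strand there has phi = 0 and the lagging
    strand phi = 1, so with strand means u0 < u1,

        beta / (1 - beta) = sqrt(odds(u0) / odds(u1)),
        kappa = 1 / sqrt(odds(u0) * odds(u1)).

    On ideal data (u0 = 0, u1 = 1) this is the identity.
    """

    background: float
    depth_ratio: float

    def phi(self, u: np.ndarray) -> np.ndarray:
        """Invert the distortion: observed usage -> synthesis fraction."""
        return _phi_from_usage(np.asarray(u, dtype=float), self.background, self.depth_ratio)


def calibrate_usage(
    usage: UsageTracks, windows: AnalysisWindows
) -> tuple[UsageTracks, UsageCalibration]:
    """Estimate (beta, kappa) from the baseline window and correct usage.

    Returns background/depth-corrected usage tracks (values are synthesis
    fractions) plus the fitted :class:`UsageCalibration`. Falls back to
    the identity when the baseline anchors are already ideal.
    """
    uw = float(_window_values(usage.u_delta_watson, windows.baseline_window).mean())
    uc = float(_window_values(usage.u_delta_crick, windows.baseline_window).mean())
    u0, u1 = sorted((uw, uc))
    eps = 1e-9
    if u0 <= eps and u1 >= 1.0 - eps:
        cal = UsageCalibration(background=0.0, depth_ratio=1.0)
    elif u0 >= u1:  # no strand asymmetry in the baseline: nothing identifiable
        cal = UsageCalibration(background=0.0, depth_ratio=1.0)
    else:
        u0c = min(max(u0, 1e-6), 0.5 - 1e-6)
        u1c = min(max(u1, 0.5 + 1e-6), 1.0 - 1e-6)
        o0 = u0c / (1.0 - u0c)
        o1 = u1c / (1.0 - u1c)
        beta_odds = math.sqrt(o0 / o1)
        beta = beta_odds / (1.0 + beta_odds)
        kappa = 1.0 / math.sqrt(o0 * o1)
        cal = UsageCalibration(
            background=float(np.clip(beta, 0.0, 0.49)),
            depth_ratio=float(np.clip(kappa, 1e-3, 1e3)),
        )

    def correct(t: Track) -> Track:
        return t.with_values(cal.phi(t.values), t.mask)

    ud_w = correct(usage.u_delta_watson)
    ud_c = correct(usage.u_delta_crick)
    corrected = UsageTracks(
        u_delta_watson=ud_w,
        u_delta_crick=ud_c,
        u_epsilon_watson=ud_w.with_values(1.0 - ud_w.values, ud_w.mask),
        u_epsilon_crick=ud_c.with_values(1.0 - ud_c.values, ud_c.mask),
    )
    return corrected, cal


def bootstrap_restart_fraction(
    usage: UsageTracks,
    windows: AnalysisWindows,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
    block_len: int = DEFAULT_BLOCK_LEN,
) -> tuple[float, float]:
    """95% CI for the restart fraction, propagating calibration noise.

    Each moving-block resample redraws the baseline window (which
    re-estimates beta, kappa and b0) and the proximal window jointly, so
    the interval reflects uncertainty in the usage calibration as well as
    in the window means. The interval is the basic (reflected) bootstrap
    interval: the calibration solve is nonlinear and skews the resampling
    distribution, and reflection around the point estimate orients that
    skew correctly. Returns (ci_low, ci_high).

    Pass the *unsmoothed* usage tracks where available: their bins carry
    independent counting noise, which the block resampling then treats
    exactly; resampling smoothed tracks in blocks of the smoothing width
    understates the window-mean variance.
    """
    uW, uC = usage.u_delta_watson, usage.u_delta_crick
    mask = uW.mask | uC.mask
    centers = uW.bin_centers()

    def window_idx(window: tuple[int, int]) -> np.ndarray:
        a, b = window
        idx = np.flatnonzero((centers >= a) & (centers < b) & ~mask)
        if idx.size < 5:
            raise WindowError(
                f"window {window} has only {idx.size} unmasked bins (need >= 5)"
            )
        return idx

    bi = window_idx(windows.baseline_window)
    pi = window_idx(windows.proximal_window)
    rng = np.random.default_rng(seed)

    def boot_idx(n: int) -> np.ndarray:
        ell = min(max(1, block_len), n)
        n_blocks = int(np.ceil(n / ell))
        starts = rng.integers(0, n - ell + 1, size=(n_boot, n_blocks))
        return (starts[:, :, None] + np.arange(ell)[None, None, :]).reshape(n_boot, -1)[:, :n]

    Wb = uW.values[bi][boot_idx(bi.size)]
    Cb = uC.values[bi][boot_idx(bi.size)]
    Wp = uW.values[pi][boot_idx(pi.size)]
    Cp = uC.values[pi][boot_idx(pi.size)]

    def f_of(Wbase, Cbase, Wprox, Cprox):
        mW, mC = Wbase.mean(axis=-1), Cbase.mean(axis=-1)
        beta, kappa = _solve_calibration(np.minimum(mW, mC), np.maximum(mW, mC))
        beta, kappa = np.atleast_1d(beta)[:, None], np.atleast_1d(kappa)[:, None]
        b0 = 0.5 * (_phi_from_usage(Wbase, beta, kappa)
                    + _phi_from_usage(Cbase, beta, kappa)).mean(axis=-1)
        bp = 0.5 * (_phi_from_usage(Wprox, beta, kappa)
                    + _phi_from_usage(Cprox, beta, kappa)).mean(axis=-1)
        denom = 1.0 - b0
        f = np.where(denom > 0, (bp - b0) / np.where(denom > 0, denom, 1.0), 1.0)
        return np.clip(f, 0.0, 1.0)

    f_star = f_of(Wb, Cb, Wp, Cp)
    f_hat = float(f_of(uW.values[bi][None, :], uC.values[bi][None, :],
                       uW.values[pi][None, :], uC.values[pi][None, :])[0])
    q_lo, q_hi = np.percentile(f_star, [2.5, 97.5])
    lo = float(np.clip(2.0 * f_hat - q_hi, 0.0, 1.0))
    hi = float(np.clip(2.0 * f_hat - q_lo, 0.0, 1.0))
    return min(lo, f_hat), max(hi, f_hat)


def estimate_background(usage: UsageTracks, windows: AnalysisWindows) -> float:
    """Background incorporation fraction beta from the baseline window.

    Convenience wrapper around :func:`calibrate_usage`; returns 0 on
    ideal (background-free) data.
    """
    _, cal = calibrate_usage(usage, windows)
    return cal.background


def estimate_baseline(
    bias: Track,
    windows: AnalysisWindows,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
    block_len: int = DEFAULT_BLOCK_LEN,
) -> BaselineEstimate:
    """Mean bias over the upstream baseline window, with block-bootstrap CI."""
    vals = _window_values(bias, windows.baseline_window)
    rng = np.random.default_rng(seed)
    boots = _block_boot_means(vals, n_boot, block_len, rng)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return BaselineEstimate(value=float(vals.mean()), ci_low=float(lo),
                            ci_high=float(hi), n_bins=int(vals.size))


def estimate_restart(
    bias: Track,
    windows: AnalysisWindows,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
    ceiling: float = 1.0,
    block_len: int = DEFAULT_BLOCK_LEN,
) -> RestartEstimate:
    """Estimate the restart fraction f at the barrier.

    ``b0`` = mean bias over the baseline window, ``b_prox`` = mean bias
    over the proximal downstream window, ``f`` =
    :func:`bias_to_restart_fraction` of the pair. The 95% CI is a
    moving-block bootstrap over bins (baseline and proximal windows
    resampled independently; block length should match the smoothing
    window), percentile 2.5/97.5, reproducible from ``seed``.
    """
    base_vals = _window_values(bias, windows.baseline_window)
    prox_vals = _window_values(bias, windows.proximal_window)
    b0 = float(base_vals.mean())
    b_prox = float(prox_vals.mean())
    f = bias_to_restart_fraction(b_prox, b0, ceiling)

    rng = np.random.default_rng(seed)
    b0_star = _block_boot_means(base_vals, n_boot, block_len, rng)
    bp_star = _block_boot_means(prox_vals, n_boot, block_len, rng)
    denom = ceiling - b0_star
    with np.errstate(divide="ignore", invalid="ignore"):
        f_star = np.where(denom > 0, (bp_star - b0_star) / np.where(denom > 0, denom, 1.0), 1.0)
    f_star = np.clip(f_star, 0.0, 1.0)
    lo, hi = np.percentile(f_star, [2.5, 97.5])
    return RestartEstimate(
        b0=b0, b_prox=b_prox, f=f, ci_low=float(lo), ci_high=float(hi),
        windows=windows, ceiling=ceiling, n_boot=n_boot, seed=seed,
    )


def estimate_progression(
    bias: Track,
    windows: AnalysisWindows,
    b0: float,
    b_prox: float | None = None,
) -> ProgressionEstimate:
    """Half-distance of the bias increment downstream of the barrier.

    ``delta0 = b_prox - b0`` is the proximal bias increment; scanning the
    (already smoothed) bias downstream from the proximal window's end,
    ``d_half`` is the distance from the barrier of the first bin whose
    increment has fallen to ``delta0 / 2`` or below (ties: smallest
    distance wins). If no bin within ``progression_range`` qualifies, the
    estimate is censored at ``progression_range``.

    Raises
    ------
    ProgressionUndefinedError
        If the increment is not positive (no restart signal).
    """
    if b_prox is None:
        b_prox = float(_window_values(bias, windows.proximal_window).mean())
    delta0 = b_prox - b0
    if delta0 <= 0:
        raise ProgressionUndefinedError(
            f"proximal bias increment {delta0:.4g} <= 0: no restart signal to track"
        )
    centers = bias.bin_centers()
    lo = windows.proximal_window[1]
    hi = windows.barrier_pos + windows.progression_range
    sel = (centers >= lo) & (centers <= hi) & ~bias.mask
    idx = np.flatnonzero(sel)
    below = idx[(bias.values[idx] - b0) <= delta0 / 2.0]
    if below.size:
        d_half = float(centers[below[0]] - windows.barrier_pos)
        return ProgressionEstimate(delta0=float(delta0), d_half=d_half, censored=False)
    return ProgressionEstimate(
        delta0=float(delta0), d_half=float(windows.progression_range), censored=True
    )


def compare_strains(
    ref: tuple[RestartEstimate, ProgressionEstimate],
    mut: tuple[RestartEstimate, ProgressionEstimate],
) -> StrainComparison:
    """Mutant-over-reference ratios of restart fraction and half-distance."""
    ref_r, ref_p = ref
    mut_r, mut_p = mut
    if ref_r.f <= 0:
        raise ComparisonError("reference restart fraction is zero; ratios undefined")
    return StrainComparison(
        relative_restart=mut_r.f / ref_r.f,
        relative_progression=mut_p.d_half / ref_p.d_half,
        ref_censored=ref_p.censored,
        mut_censored=mut_p.censored,
    )
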