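"""High-level orchestration: tetrad -> usage -> bias -> restart report.

These are the functions the CLI, the examples and most tests call; each
step is also available individually from the lower modules.
"""

from __future__ import annotations

from dataclasses import dataclass

from .restart import (
    AnalysisWindows,
    ProgressionEstimate,
    RestartEstimate,
    bootstrap_restart_fraction,
    calibrate_usage,
    delta_delta_bias,
    estimate_progression,
    estimate_restart,
)
from .tracks import CountTetrad, Track
from .usage import UsageTracks, compute_usage, normalize_libraries, smooth_usage

__all__ = ["RestartReport", "usage_pipeline", "quantify_restart", "analyze_tetrad"]

DEFAULT_SMOOTH_BINS = 5


@dataclass
class RestartReport:
    """Bundle of everything the restart analysis produces for one strain."""

    restart: RestartEstimate
    progression: ProgressionEstimate
    background: float

    def to_dict(self) -> dict:
        return {
            "restart": self.restart.to_dict(),
            "progression": self.progression.to_dict(),
            "background": self.background,
        }


def usage_pipeline(tetrad: CountTetrad, smooth_bins: int = DEFAULT_SMOOTH_BINS) -> UsageTracks:
    """Normalize a count tetrad, form usage fractions, and smooth them.

    Smoothing is applied to the usage fractions, not the raw counts, so
    Poisson noise is averaged on the feature scale (~250 bp by default)
    without mixing the two libraries' depths. Depth normalization is per
    library (see :func:`forkrestart.usage.normalize_libraries`).
    """
    usage = compute_usage(normalize_libraries(tetrad))
    return smooth_usage(usage, smooth_bins)


def quantify_restart(
    usage: UsageTracks,
    windows: AnalysisWindows,
    n_boot: int = 1000,
    seed: int | None = None,
    correct_background: bool = True,
    block_len: int = DEFAULT_SMOOTH_BINS,
    raw_usage: UsageTracks | None = None,
) -> RestartReport:
    """Full restart analysis of one strain's (smoothed) usage tracks.

    Calibrates observed usage against the baseline window (background
    incorporation and residual library depth ratio; skipped when
    ``correct_background`` is False), computes the delta/delta bias on
    the corrected tracks, then the restart fraction with bootstrap CI
    and the progression half-distance.

    When ``raw_usage`` (the unsmoothed tracks) is supplied, the bootstrap
    resamples those instead of the smoothed ones: unsmoothed bins carry
    independent counting noise, so the resampled window means have the
    correct variance, whereas resampling smoothed bins in short blocks
    understates it. Window means themselves are insensitive to smoothing,
    so point estimates are unchanged.
    """
    boot_source = raw_usage if raw_usage is not None else usage
    if correct_background:
        cal_usage, cal = calibrate_usage(usage, windows)
        beta = cal.background
    else:
        cal_usage, beta = usage, 0.0
    bias = delta_delta_bias(cal_usage)
    est = estimate_restart(
        bias, windows, n_boot=n_boot, seed=seed, ceiling=1.0, block_len=block_len
    )
    if correct_background:
        # full-pipeline bootstrap: includes calibration uncertainty
        lo, hi = bootstrap_restart_fraction(
            boot_source, windows, n_boot=n_boot, seed=seed, block_len=block_len
        )
        est.ci_low, est.ci_high = min(lo, est.f), max(hi, est.f)
    prog = estimate_progression(bias, windows, b0=est.b0, b_prox=est.b_prox)
    return RestartReport(restart=est, progression=prog, background=beta)


def analyze_tetrad(
    tetrad: CountTetrad,
    windows: AnalysisWindows,
    smooth_bins: int = DEFAULT_SMOOTH_BINS,
    n_boot: int = 1000,
    seed: int | None = None,
    correct_background: bool = True,
) -> RestartReport:
    """One-call analysis of a raw count tetrad.

    Normalizes per library, forms usage fractions, smooths them for the
    bias track and the half-distance scan, and estimates the restart
    fraction with a bootstrap that resamples the unsmoothed usage bins.
    """
    raw = compute_usage(normalize_libraries(tetrad))
    smoothed = smooth_usage(raw, smooth_bins)
    return quantify_restart(
        smoothed, windows, n_boot=n_boot, seed=seed,
        correct_background=correct_background, block_len=smooth_bins,
        raw_usage=raw,
    )


def bias_track(usage: UsageTracks) -> Track:
    """Convenience re-export of :func:`forkrestart.restart.delta_delta_bias`."""
    return delta_delta_bias(usage)
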