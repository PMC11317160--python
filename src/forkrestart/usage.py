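"""Polymerase usage fractions from Pu-Seq count tetrads.

Pu-Seq compares ribonucleotide densities between a Pol delta-mutant and a
Pol epsilon-mutant library on each strand: after depth normalization, the
fraction of DNA on strand ``s`` synthesized by Pol delta is estimated as

    U_delta^s = d_s / (d_s + e_s),      U_epsilon^s = 1 - U_delta^s,

the unique ratio form under which the two usages on a strand sum to one
and ideal data hit the bias anchor points 0.5 (canonical) and 1.0 (fully
restarted). Normalization is per-library mean-to-one scaling, which makes
the two libraries comparable and is invariant to sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NormalizationError, ParameterError
from .tracks import CountTetrad, Track

__all__ = ["UsageTracks", "normalize_tetrad", "normalize_libraries", "compute_usage",
           "smooth_track", "smooth_usage"]


@dataclass
class UsageTracks:
    """Per-strand Pol delta / Pol epsilon usage fractions.

    For every unmasked bin and strand, ``u_delta + u_epsilon == 1`` and all
    values lie in [0, 1]. Bins where both libraries report zero signal are
    masked (the ratio is undefined there). No complementarity is imposed
    *across* strands: U_delta^W + U_delta^C departs from 1 exactly where
    restarted delta/delta synthesis appears, and that departure is the
    signal downstream modules quantify.
    """

    u_delta_watson: Track
    u_delta_crick: Track
    u_epsilon_watson: Track
    u_epsilon_crick: Track

    def __post_init__(self) -> None:
        ref = self.u_delta_watson
        for t in (self.u_delta_crick, self.u_epsilon_watson, self.u_epsilon_crick):
            if not ref.same_binning(t):
                raise ParameterError("usage tracks must share one binning")


def normalize_tetrad(tetrad: CountTetrad) -> CountTetrad:
    """Rescale each library track so its mean over unmasked bins is one.

    Relative bin-to-bin structure is unchanged; this only absorbs the
    (arbitrary) sequencing depth of each library.

    Raises
    ------
    NormalizationError
        If a library has no positive unmasked counts.
    """
    out = {}
    for role, t in tetrad.items():
        valid = ~t.mask
        mean = t.values[valid].mean() if valid.any() else 0.0
        if mean <= 0:
            raise NormalizationError(f"library {role!r} has no signal (mean {mean})")
        out[role] = t.with_values(t.values / mean, t.mask)
    return CountTetrad(
        d_watson=out["delta_watson"],
        d_crick=out["delta_crick"],
        e_watson=out["epsilon_watson"],
        e_crick=out["epsilon_crick"],
    )


def normalize_libraries(tetrad: CountTetrad) -> CountTetrad:
    """Rescale each *library* (both strands jointly) to mean one.

    The two strand tracks of one Pu-Seq library come from the same
    sequencing run and share its depth, so depth correction must apply
    one factor per library, not one per track: scaling each strand
    separately forces the strands' means equal and distorts usage ratios
    wherever Pol delta's share of total synthesis departs from one half
    (exactly what happens across a restart locus). This is the
    normalization the analysis pipeline uses; :func:`normalize_tetrad`
    (per-track) remains available for symmetric, genome-scale inputs.
    """
    pairs = {"delta": (tetrad.d_watson, tetrad.d_crick),
             "epsilon": (tetrad.e_watson, tetrad.e_crick)}
    scaled = {}
    for lib, (w, c) in pairs.items():
        vals = np.concatenate([w.values[~w.mask], c.values[~c.mask]])
        mean = vals.mean() if vals.size else 0.0
        if mean <= 0:
            raise NormalizationError(f"library {lib!r} has no signal (mean {mean})")
        scaled[lib] = (w.with_values(w.values / mean, w.mask),
                       c.with_values(c.values / mean, c.mask))
    return CountTetrad(
        d_watson=scaled["delta"][0], d_crick=scaled["delta"][1],
        e_watson=scaled["epsilon"][0], e_crick=scaled["epsilon"][1],
    )


def _usage_pair(d: Track, e: Track) -> tuple[Track, Track]:
    tot = d.values + e.values
    mask = d.mask | e.mask | (tot <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(tot > 0, d.values / np.where(tot > 0, tot, 1.0), 0.0)
    u = np.clip(u, 0.0, 1.0)
    ud = d.with_values(u, mask)
    ue = d.with_values(1.0 - u, mask)
    return ud, ue

def compute_usage(tetrad_norm: CountTetrad) -> UsageTracks:
    """Per-bin, per-strand usage fractions from a normalized tetrad.

    ``U_delta^s = d_s / (d_s + e_s)``; bins with ``d_s + e_s == 0`` are
    masked. Call :func:`normalize_tetrad` first so the two libraries are
    on a common depth scale.
    """
    udw, uew = _usage_pair(tetrad_norm.d_watson, tetrad_norm.e_watson)
    udc, uec = _usage_pair(tetrad_norm.d_crick, tetrad_norm.e_crick)
    return UsageTracks(
        u_delta_watson=udw, u_delta_crick=udc,
        u_epsilon_watson=uew, u_epsilon_crick=uec,
    )


def smooth_track(track: Track, window_bins: int) -> Track:
    """Centered moving average over unmasked bins.

    Masked bins are excluded from both numerator and denominator; a bin
    whose whole window is masked stays masked. ``window_bins`` must be odd
    (so the window is centered); 1 is the identity.
    """
    if window_bins < 1 or window_bins % 2 == 0:
        raise ParameterError(f"window_bins must be a positive odd integer, got {window_bins}")
    if window_bins == 1:
        return track.with_values(track.values.copy(), track.mask.copy())
    valid = (~track.mask).astype(float)
    kernel = np.ones(window_bins)
    num = np.convolve(track.values * valid, kernel, mode="same")
    den = np.convolve(valid, kernel, mode="same")
    mask = den <= 0
    vals = np.where(mask, 0.0, num / np.where(mask, 1.0, den))
    return track.with_values(vals, mask)


def smooth_usage(usage: UsageTracks, window_bins: int) -> UsageTracks:
    """Apply :func:`smooth_track` to all four usage tracks."""
    return UsageTracks(
        u_delta_watson=smooth_track(usage.u_delta_watson, window_bins),
        u_delta_crick=smooth_track(usage.u_delta_crick, window_bins),
        u_epsilon_watson=smooth_track(usage.u_epsilon_watson, window_bins),
        u_epsilon_crick=smooth_track(usage.u_epsilon_crick, window_bins),
    )
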