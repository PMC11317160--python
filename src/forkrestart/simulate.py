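"""Forward stochastic simulator of replication across a polar fork barrier.

Each simulated cell replicates a linear locus from a set of origins. An
origin fires at a truncated-positive normal time and sends two forks
outward at speed ``v``. Canonical forks assign polymerases by direction:
a rightward fork synthesizes Watson with Pol epsilon (leading) and Crick
with Pol delta (lagging); a leftward fork the reverse. A rightward fork
reaching the barrier arrests with probability ``p_block`` (the barrier is
polar: leftward forks are never affected). An arrested fork restarts with
probability ``p_restart`` after a delay ``T``; restarted synthesis
resumes ``resection_len`` bp behind the barrier (re-synthesizing the
resected nascent strand) and proceeds rightward at ``v_r`` with BOTH
strands made by Pol delta, insensitive to the barrier, until it meets the
converging canonical fork. A non-restarting (or not-yet-restarted)
arrested fork is rescued by the converging fork; a fork rescued before
its restart delay elapses counts as not restarted.

Kinematics are event-driven and continuous in time — fork meetings are
resolved at exact positions — and each bin inherits the polymerase of
the fork that covered its midpoint. Aggregating cells gives per-strand
Pol delta synthesis fractions (the ground-truth provenance); Pu-Seq-like
counts are Poisson draws around ``depth * (beta + (1 - 2 beta) * phi)``
per library and strand, where ``beta`` is background incorporation by
the non-mutated polymerase.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass

import numpy as np
import yaml

from .errors import ConfigError, SimulationError
from .tracks import CountTetrad, Track, TETRAD_ROLES

__all__ = [
    "SimConfig",
    "ProvenanceSummary",
    "simulate_cell",
    "simulate_locus",
    "sample_counts",
    "generate_dataset",
]

POL_EPSILON = 0
POL_DELTA = 1

#: default origins: (position bp, firing-time mean min, firing-time sd min).
#: The early origin delivers the rightward fork to the barrier ~35 min in;
#: the late, downstream origin fires late enough that restarted forks
#: progress ~10 kb before terminating against its leftward fork, the
#: progression scale seen at this kind of locus.
DEFAULT_ORIGINS = ((5_000, 10.0, 2.0), (55_000, 50.0, 5.0))


@dataclass
class SimConfig:
    """Full parameterization of the locus replication simulator.

    Units: positions/lengths bp, times min, speeds bp/min.
    ``restart_speed=None`` means "same as fork_speed". ``background`` is
    the fraction of ribonucleotide signal contributed by the non-mutated
    polymerase; ``depth`` the expected counts per bin per library where
    usage is 1.
    """

    seed: int
    locus_length: int = 60_000
    bin_width: int = 50
    origins: tuple = DEFAULT_ORIGINS
    fork_speed: float = 1_000.0
    barrier_pos: int = 30_000
    p_block: float = 0.9
    p_restart: float = 0.9
    restart_delay: float = 20.0
    restart_speed: float | None = None
    resection_len: int = 1_000
    background: float = 0.05
    depth: float = 100.0
    n_cells: int = 5_000
    ref_name: str = "locus"

    def __post_init__(self) -> None:
        self.origins = tuple(tuple(o) for o in self.origins)
        if self.restart_speed is None:
            self.restart_speed = float(self.fork_speed)
        for name in ("p_block", "p_restart"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        if min(self.fork_speed, self.restart_speed) <= 0:
            raise ConfigError("fork speeds must be positive")
        if self.locus_length <= 0 or self.bin_width <= 0 or self.depth < 0:
            raise ConfigError("locus_length, bin_width must be positive; depth >= 0")
        if not 0.0 <= self.background < 0.5:
            raise ConfigError(f"background must be in [0, 0.5), got {self.background}")
        if self.restart_delay < 0 or self.resection_len < 0:
            raise ConfigError("restart_delay and resection_len must be >= 0")
        if not self.origins:
            raise ConfigError("at least one origin is required")
        pos = [o[0] for o in self.origins]
        if not all(0 <= p <= self.locus_length for p in pos):
            raise ConfigError("origin positions must lie within the locus")
        if len(self.origins) >= 2:
            left = min(pos)
            right = max(pos)
            if not left < self.barrier_pos < right:
                raise ConfigError(
                    f"barrier {self.barrier_pos} must lie strictly between the outermost "
                    f"origins ({left}, {right})"
                )
        if self.n_cells < 1:
            raise ConfigError("n_cells must be >= 1")

    @property
    def n_bins(self) -> int:
        return int(math.ceil(self.locus_length / self.bin_width))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["origins"] = [list(o) for o in self.origins]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = set(cls.__dataclass_fields__)
        extra = set(d) - known
        if extra:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(extra))}")
        if "seed" not in d:
            raise ConfigError("config must provide a seed")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path, "rt") as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(d)


@dataclass
class ProvenanceSummary:
    """Ground-truth per-strand Pol delta synthesis fractions over cells.

    ``phi_delta_watson[i]`` is the fraction of cells in which bin i's
    Watson nascent strand was synthesized by Pol delta (Pol epsilon
    fraction is the complement: every bin is replicated exactly once per
    cell). Restart bookkeeping: ``realized_restart_fraction`` =
    n_restarted / n_cells (fraction of all cells in which a restarted
    fork actually resumed synthesis — the quantity the bias increment
    measures); the arrest-conditional rate is ``conditional_restart_fraction``.
    """

    phi_delta_watson: Track
    phi_delta_crick: Track
    n_cells: int
    n_arrested: int
    n_restarted: int
    config: SimConfig

    @property
    def realized_restart_fraction(self) -> float:
        return self.n_restarted / self.n_cells

    @property
    def conditional_restart_fraction(self) -> float:
        return self.n_restarted / self.n_arrested if self.n_arrested else float("nan")

    @property
    def phi_epsilon_watson(self) -> Track:
        t = self.phi_delta_watson
        return t.with_values(1.0 - t.values, t.mask)

    @property
    def phi_epsilon_crick(self) -> Track:
        t = self.phi_delta_crick
        return t.with_values(1.0 - t.values, t.mask)


class _Fork:
    __slots__ = ("pos", "t", "direction", "speed", "state", "origin_pos",
                 "restart_time", "is_restarted", "barrier_tested", "seg_start")

    MOVING = 0
    ARRESTED = 1          # permanently arrested (no restart drawn)
    PENDING_RESTART = 2   # arrested, restart scheduled at restart_time

    def __init__(self, pos: float, t: float, direction: int, speed: float):
        self.pos = pos
        self.t = t
        self.direction = direction
        self.speed = speed
        self.state = _Fork.MOVING
        self.origin_pos = pos
        self.restart_time = math.inf
        self.is_restarted = False
        self.barrier_tested = False
        self.seg_start = pos

    def pos_at(self, t: float) -> float:
        if self.state == _Fork.MOVING:
            return self.pos + self.direction * self.speed * (t - self.t)
        return self.pos

    def advance(self, t: float) -> None:
        self.pos = self.pos_at(t)
        self.t = t


def _truncated_normal(mean: float, sd: float, rng: np.random.Generator) -> float:
    """Normal(mean, sd) truncated to positive times (rejection sampling)."""
    if sd <= 0:
        return max(mean, 0.0)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > 0:
            return x
    return max(mean, 1e-6)  # pragma: no cover - pathological mean << -sd


def simulate_cell(cfg: SimConfig, rng: np.random.Generator):
    """Replicate the locus once; return per-strand polymerase assignments.

    Returns
    -------
    watson, crick : int8 arrays (n_bins,)
        Per-bin nascent-strand polymerase, ``POL_DELTA`` or ``POL_EPSILON``.
    arrested, restarted : bool
        Whether a rightward fork arrested at the barrier in this cell, and
        whether that arrested fork actually resumed delta/delta synthesis.

    Raises
    ------
    SimulationError
        If the configuration leaves an interval unreplicated (no
        converging fork and no restart).
    """
    L = float(cfg.locus_length)
    barrier = float(cfg.barrier_pos)
    v = float(cfg.fork_speed)

    # pending origins ordered by firing time
    pending = sorted(
        ((_truncated_normal(mu, sd, rng), float(pos)) for pos, mu, sd in cfg.origins),
    )
    active: list[_Fork] = []  # kept sorted by position
    canon_segs: list[tuple[float, float, int]] = []   # (a, b, direction)
    delta_segs: list[tuple[float, float]] = []        # restarted delta/delta intervals
    arrested = False
    restarted = False
    t_now = 0.0

    def covered(x: float, t: float) -> bool:
        for a, b, _ in canon_segs:
            if a <= x <= b:
                return True
        for a, b in delta_segs:
            if a <= x <= b:
                return True
        for f in active:
            lo, hi = sorted((f.seg_start, f.pos_at(t)))
            if lo <= x <= hi:
                return True
        return False

    def finish_canonical(f: _Fork, end_pos: float) -> None:
        a, b = sorted((f.seg_start, end_pos))
        canon_segs.append((a, b, f.direction))

    guard = 0
    while pending or active:
        guard += 1
        if guard > 10_000:  # pragma: no cover - defensive
            raise SimulationError("event loop failed to terminate")

        # --- gather candidate events: (time, priority, kind, payload) ---
        best = None

        if pending:
            best = (pending[0][0], 0, "fire", None)

        for f in active:
            if f.state == _Fork.PENDING_RESTART:
                ev = (f.restart_time, 1, "restart", f)
                if best is None or ev[:2] < best[:2]:
                    best = ev
            elif f.state == _Fork.MOVING:
                # polar barrier: only rightward forks are tested
                if (f.direction > 0 and not f.barrier_tested and f.pos < barrier):
                    tb = f.t + (barrier - f.pos) / f.speed
                    ev = (tb, 2, "barrier", f)
                    if best is None or ev[:2] < best[:2]:
                        best = ev
                edge = L if f.direction > 0 else 0.0
                te = f.t + abs(edge - f.pos) / f.speed
                ev = (te, 4, "edge", f)
                if best is None or ev[:2] < best[:2]:
                    best = ev

        # meetings between adjacent converging forks (A rightward left of B leftward)
        for i in range(len(active) - 1):
            A, B = active[i], active[i + 1]
            if A.direction <= 0 or B.direction >= 0:
                continue
            sa = A.speed if A.state == _Fork.MOVING else 0.0
            sb = B.speed if B.state == _Fork.MOVING else 0.0
            pa = A.pos_at(t_now)
            pb = B.pos_at(t_now)
            if sa + sb <= 0:
                continue
            tm = t_now + max(pb - pa, 0.0) / (sa + sb)
            # a rightward fork still due a barrier test stops there first
            if (A.state == _Fork.MOVING and not A.barrier_tested
                    and pa < barrier and A.pos_at(tm) > barrier):
                continue
            ev = (tm, 3, "meet", (A, B))
            if best is None or ev[:2] < best[:2]:
                best = ev

        if best is None:  # pragma: no cover - only arrested forks left, no rescue
            break

        t_ev, _, kind, payload = best
        t_now = t_ev

        if kind == "fire":
            t_fire, pos = pending.pop(0)
            if covered(pos, t_now):
                continue  # passively replicated before firing
            left = _Fork(pos, t_now, -1, v)
            right = _Fork(pos, t_now, +1, v)
            active.extend((left, right))
            active.sort(key=lambda f: f.pos_at(t_now))
        elif kind == "barrier":
            f = payload
            f.advance(t_now)
            f.barrier_tested = True
            if rng.random() < cfg.p_block:
                arrested = True
                if rng.random() < cfg.p_restart:
                    f.state = _Fork.PENDING_RESTART
                    f.restart_time = t_now + cfg.restart_delay
                else:
                    f.state = _Fork.ARRESTED
        elif kind == "restart":
            f = payload
            # canonical synthesis ran from the origin to the barrier; the
            # restarted fork re-synthesizes the resected interval delta/delta
            finish_canonical(f, f.pos)
            f.seg_start = max(f.pos - cfg.resection_len, 0.0)
            f.pos = f.seg_start
            f.t = t_now
            f.speed = float(cfg.restart_speed)
            f.state = _Fork.MOVING
            f.is_restarted = True
            restarted = True
        elif kind == "meet":
            A, B = payload
            A.advance(t_now)
            B.advance(t_now)
            m = 0.5 * (A.pos + B.pos)  # equal only up to fp rounding
            if A.is_restarted:
                delta_segs.append((A.seg_start, m))
            else:
                finish_canonical(A, m)
            finish_canonical(B, m)
            active.remove(A)
            active.remove(B)
        elif kind == "edge":
            f = payload
            f.advance(t_now)
            if f.is_restarted:
                delta_segs.append((f.seg_start, f.pos))
            else:
                finish_canonical(f, f.pos)
            active.remove(f)

    # --- rasterize: bins inherit the fork covering their midpoint ---
    n_bins = cfg.n_bins
    bw = float(cfg.bin_width)
    watson = np.full(n_bins, -1, dtype=np.int8)
    crick = np.full(n_bins, -1, dtype=np.int8)

    def bin_range(a: float, b: float) -> tuple[int, int]:
        # bins whose center (k + 0.5) * bw lies in [a, b)
        k0 = max(0, math.ceil(a / bw - 0.5))
        k1 = min(n_bins, math.ceil(b / bw - 0.5))
        return k0, k1

    for a, b, direction in canon_segs:
        k0, k1 = bin_range(a, b)
        if k0 >= k1:
            continue
        if direction > 0:   # rightward: Watson leading (eps), Crick lagging (delta)
            watson[k0:k1] = POL_EPSILON
            crick[k0:k1] = POL_DELTA
        else:
            watson[k0:k1] = POL_DELTA
            crick[k0:k1] = POL_EPSILON
    # restarted delta/delta synthesis overwrites (incl. resected interval)
    for a, b in delta_segs:
        k0, k1 = bin_range(a, b)
        watson[k0:k1] = POL_DELTA
        crick[k0:k1] = POL_DELTA

    if np.any(watson < 0):
        holes = np.flatnonzero(watson < 0)
        lo = holes[0] * cfg.bin_width
        hi = (holes[-1] + 1) * cfg.bin_width
        raise SimulationError(
            f"configuration leaves interval [{lo}, {hi}) unreplicated "
            f"(no converging fork and no restart reaches it)"
        )
    return watson, crick, arrested, restarted


def simulate_locus(cfg: SimConfig) -> ProvenanceSummary:
    """Aggregate ``cfg.n_cells`` independent cells into provenance fractions.

    Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    n_bins = cfg.n_bins
    acc_w = np.zeros(n_bins, dtype=np.float64)
    acc_c = np.zeros(n_bins, dtype=np.float64)
    n_arr = 0
    n_res = 0
    for _ in range(cfg.n_cells):
        w, c, arrested, restarted = simulate_cell(cfg, rng)
        acc_w += w
        acc_c += c
        n_arr += arrested
        n_res += restarted
    mk = dict(ref_name=cfg.ref_name, bin_width=cfg.bin_width, start=0)
    return ProvenanceSummary(
        phi_delta_watson=Track(values=acc_w / cfg.n_cells, **mk),
        phi_delta_crick=Track(values=acc_c / cfg.n_cells, **mk),
        n_cells=cfg.n_cells,
        n_arrested=n_arr,
        n_restarted=n_res,
        config=cfg,
    )


def sample_counts(
    prov: ProvenanceSummary,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> CountTetrad:
    """Draw Pu-Seq-like Poisson counts from provenance fractions.

    For library L (delta- or epsilon-mutant) and strand s the per-bin
    mean is ``depth * ((1 - beta) * phi_L^s + beta * (1 - phi_L^s))``:
    the mutated polymerase contributes where it synthesized, the
    non-mutated one a background fraction ``beta`` elsewhere.
    """
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 1])
    beta = cfg.background
    D = cfg.depth

    def draw(phi: Track) -> Track:
        lam = D * ((1.0 - beta) * phi.values + beta * (1.0 - phi.values))
        return phi.with_values(rng.poisson(np.clip(lam, 0.0, None)).astype(float))

    return CountTetrad(
        d_watson=draw(prov.phi_delta_watson),
        d_crick=draw(prov.phi_delta_crick),
        e_watson=draw(prov.phi_epsilon_watson),
        e_crick=draw(prov.phi_epsilon_crick),
    )


_COUNT_FILES = {role: f"counts_{role}.bedgraph" for role in TETRAD_ROLES}
_PROV_FILES = {
    "phi_delta_watson": "phi_delta_watson.bedgraph",
    "phi_delta_crick": "phi_delta_crick.bedgraph",
    "phi_epsilon_watson": "phi_epsilon_watson.bedgraph",
    "phi_epsilon_crick": "phi_epsilon_crick.bedgraph",
}


def generate_dataset(cfg: SimConfig, out_dir) -> dict:
    """Simulate, sample counts, and write a complete dataset to ``out_dir``.

    Writes the four count bedGraphs, the four ground-truth provenance
    bedGraphs, a ``truth.json`` (realized restart bookkeeping + config)
    and a ``manifest.json`` mapping tetrad roles to files (consumable by
    :func:`forkrestart.tracks.load_tetrad`). Byte-for-byte reproducible
    from the config (which includes the seed). Returns the manifest dict.
    """
    from .tracks import write_bedgraph  # local to avoid cycle at import time

    os.makedirs(out_dir, exist_ok=True)
    prov = simulate_locus(cfg)
    tetrad = sample_counts(prov, cfg)

    for role, tr in tetrad.items():
        write_bedgraph(tr, os.path.join(out_dir, _COUNT_FILES[role]))
    for attr, fname in _PROV_FILES.items():
        write_bedgraph(getattr(prov, attr), os.path.join(out_dir, fname))

    truth = {
        "realized_restart_fraction": prov.realized_restart_fraction,
        "conditional_restart_fraction": prov.conditional_restart_fraction,
        "n_cells": prov.n_cells,
        "n_arrested": prov.n_arrested,
        "n_restarted": prov.n_restarted,
        "config": cfg.to_dict(),
    }
    with open(os.path.join(out_dir, "truth.json"), "wt") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")

    manifest = {
        "ref_name": cfg.ref_name,
        "bin_width": cfg.bin_width,
        "barrier_pos": cfg.barrier_pos,
        "seed": cfg.seed,
        "roles": dict(_COUNT_FILES),
        "provenance": dict(_PROV_FILES),
        "truth": "truth.json",
    }
    with open(os.path.join(out_dir, "manifest.json"), "wt") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
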