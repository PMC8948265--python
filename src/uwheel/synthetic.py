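"""Synthetic-data generators with known ground truth.

Everything the pipeline consumes can be generated here: swarms with
mode-specific radius laws, branching networks with inclines, and noisy
16-bit fluorescence scan pairs whose per-branch bead fractions are known
exactly.  A single root seed fans out to per-stage child seeds so each
stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .network import Junction, Network, check_network
from .params import ModelParams, default_params
from .quantify import DEFAULT_CUTOFF, FluorescenceScan, RoiSet
from .swarm import SwarmMode, SwarmState, get_mode, sample_radii

__all__ = [
    "GeneratorSpec",
    "gen_swarm",
    "gen_network",
    "mca_network",
    "gen_scan_pair",
    "child_rngs",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Declarative spec for the `uwheel gen` pipeline."""

    seed: int = 0
    swarm_mode: str = "rolling"
    swarm_count: int = 500
    swarm_overrides: dict = field(default_factory=dict)
    network_depth: int = 3
    incline_range_deg: tuple[float, float] = (0.0, 45.0)
    segment_mm: tuple[float, float] = (3.0, 6.0)
    parallel_prob: float = 0.5
    scan_shape: tuple[int, int] = (256, 256)
    scan_amplitude: int = 20000
    background_max: int = 3000
    noise: str = "poisson"

    def __post_init__(self) -> None:
        lo, hi = self.incline_range_deg
        if not (-90.0 < lo <= hi < 90.0):
            raise ConfigError("incline range must lie within (-90, 90) deg")
        if self.swarm_count <= 0 or self.network_depth <= 0:
            raise ConfigError("counts must be > 0")


def child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Fan a root seed out into n independent child generators."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def gen_swarm(
    mode: str | SwarmMode,
    count: int,
    seed: int | np.random.Generator,
    params: ModelParams | None = None,
    **overrides,
) -> SwarmState:
    """Sample a swarm: radii from the mode's truncated law, the rest derived."""
    params = params or default_params()
    m = get_mode(mode, **overrides) if isinstance(mode, str) else mode
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    R = sample_radii(m, count, rng)
    return SwarmState.from_radii(R, m, params)


# ---------------------------------------------------------------------------
def gen_network(
    seed: int | np.random.Generator = 0,
    depth: int = 3,
    incline_range_deg: tuple[float, float] = (0.0, 45.0),
    segment_mm: tuple[float, float] = (3.0, 6.0),
    parallel_prob: float = 0.5,
    channel_diameter: float = 0.6e-3,
    target: str | None = None,
) -> Network:
    """Random branching network: a trunk with ``depth - 1`` turns.

    ``depth`` counts tree levels: depth 1 is a straight turn-free path;
    each deeper level adds a turn forking a terminal side branch and a
    continuation, and the final turn forks two terminals.  Inclines are
    drawn uniformly from ``incline_range_deg``; with probability
    ``parallel_prob`` a turn gets a parallel-channel mouth annotated
    ~1 segment downstream.
    """
    if depth < 1:
        raise ConfigError("depth must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo_phi, hi_phi = incline_range_deg
    lo_s, hi_s = (s * 1e-3 for s in segment_mm)

    def phi() -> float:
        return float(rng.uniform(lo_phi, hi_phi))

    def seg() -> float:
        return float(rng.uniform(lo_s, hi_s))

    junctions: dict[str, Junction] = {}
    branches: dict[str, tuple[str, ...]] = {}
    terminals: list[str] = []
    x = 0.0
    junctions["J0"] = Junction("J0", 0.0, phi())
    trunk = ["J0"]
    if depth == 1:
        junctions["E0"] = Junction("E0", seg(), phi(), kind="terminal")
        branches["trunk"] = ("J0", "E0")
        return check_network(
            Network(
                junctions=junctions, branches=branches, root="trunk",
                target="trunk", channel_diameter=channel_diameter,
            )
        )
    n_turns = depth - 1
    branch_idx = 0
    for d in range(n_turns):
        x += seg()
        last = d == n_turns - 1
        kids = []
        for _ in range(2 if last else 1):
            branch_idx += 1
            kids.append(f"b{branch_idx}")
        if not last:
            kids.append(f"m{d + 1}")
        offsets = ()
        if rng.random() < parallel_prob:
            offsets = (x + seg(),)
        tid = f"T{d + 1}"
        junctions[tid] = Junction(
            tid, x, phi(), kind="turn", children=tuple(kids),
            parallel_offsets=offsets,
        )
        trunk.append(tid)
        branches["trunk" if d == 0 else f"m{d}"] = tuple(trunk)
        # terminal side branch(es)
        for bid in kids:
            if bid.startswith("m"):
                continue
            eid = f"E{bid[1:]}"
            junctions[eid] = Junction(eid, x + seg(), phi(), kind="terminal")
            branches[bid] = (tid, eid)
            terminals.append(bid)
        trunk = [tid]
    net = Network(
        junctions=junctions,
        branches=branches,
        root="trunk",
        target=target or terminals[-1],
        channel_diameter=channel_diameter,
    )
    return check_network(net)


def mca_network(target: str = "branch1") -> Network:
    """Six-terminal preset inspired by a murine middle-cerebral-artery cast.

    A ~30 mm trunk with five turns; turns 1-4 each shed one terminal
    branch and the fifth forks into two, giving terminal branches
    branch1..branch6 (1 to 5 intermediary turns from the start).
    Channel diameter 0.6 mm.  Angles are declared directly — this is a
    geometry fixture, not a mesh import.
    """
    mm = 1e-3
    J = Junction
    junctions = {
        "J0": J("J0", 0.0, 0.0),
        "J1": J("J1", 6 * mm, 10.0),
        "T1": J("T1", 14 * mm, 20.0, kind="turn",
                children=("branch1", "main2"),
                parallel_offsets=(16 * mm,)),
        "E1": J("E1", 17 * mm, 30.0, kind="terminal"),
        "J2": J("J2", 18 * mm, 5.0),
        "T2": J("T2", 21 * mm, -10.0, kind="turn",
                children=("branch2", "main3")),
        "E2": J("E2", 24 * mm, 15.0, kind="terminal"),
        "T3": J("T3", 25 * mm, 10.0, kind="turn",
                children=("branch3", "main4"),
                parallel_offsets=(27 * mm,)),
        "E3": J("E3", 28 * mm, 25.0, kind="terminal"),
        "J3": J("J3", 27 * mm, 0.0),
        "T4": J("T4", 29 * mm, 15.0, kind="turn",
                children=("branch4", "main5")),
        "E4": J("E4", 32 * mm, 20.0, kind="terminal"),
        "T5": J("T5", 32.5 * mm, 5.0, kind="turn",
                children=("branch5", "branch6")),
        "E5": J("E5", 35 * mm, 30.0, kind="terminal"),
        "E6": J("E6", 36 * mm, -5.0, kind="terminal"),
    }
    branches = {
        "trunk": ("J0", "J1", "T1"),
        "branch1": ("T1", "E1"),
        "main2": ("T1", "J2", "T2"),
        "branch2": ("T2", "E2"),
        "main3": ("T2", "T3"),
        "branch3": ("T3", "E3"),
        "main4": ("T3", "J3", "T4"),
        "branch4": ("T4", "E4"),
        "main5": ("T4", "T5"),
        "branch5": ("T5", "E5"),
        "branch6": ("T5", "E6"),
    }
    return check_network(
        Network(
            junctions=junctions, branches=branches, root="trunk",
            target=target, channel_diameter=0.6e-3,
        )
    )


# ---------------------------------------------------------------------------
def gen_scan_pair(
    fractions: dict[str, float],
    seed: int | np.random.Generator = 0,
    shape: tuple[int, int] = (256, 256),
    amplitude: int = 20000,
    background_max: int = 3000,
    noise: str = "poisson",
    injection_roi: str = "injection",
) -> tuple[FluorescenceScan, FluorescenceScan, RoiSet, dict[str, float]]:
    """Pre/post fluorescence scan pair with known per-branch fractions.

    The pre scan puts all bead signal in the injection ROI; the post scan
    lights a number of pixels proportional to each branch fraction inside
    that branch's ROI at the same per-pixel amplitude, so the quantify
    stage recovers the fractions up to pixel-count rounding and shot
    noise.  Background is drawn strictly below the default threshold.
    ``noise`` is ``"poisson"`` (shot noise on lit pixels) or ``"none"``.
    """
    total_frac = sum(fractions.values())
    if total_frac > 1.0 + 1e-12:
        raise ConfigError("branch mass fractions must sum to <= 1")
    if any(f < 0 for f in fractions.values()):
        raise ConfigError("branch mass fractions must be >= 0")
    if noise not in ("poisson", "none"):
        raise ConfigError("noise must be 'poisson' or 'none'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    names = [injection_roi] + sorted(fractions)
    rois = _block_rois(shape, names)
    inj_mask = rois.masks[injection_roi]
    n_inj = int(inj_mask.sum())

    def lit(n_pix: int) -> np.ndarray:
        if noise == "poisson":
            vals = rng.poisson(amplitude, size=n_pix)
        else:
            vals = np.full(n_pix, amplitude, dtype=np.int64)
        return np.clip(vals, DEFAULT_CUTOFF, 65535).astype(np.uint16)

    def background() -> np.ndarray:
        if background_max <= 0:
            return np.zeros(shape, dtype=np.uint16)
        return rng.integers(
            0, min(background_max, DEFAULT_CUTOFF), size=shape, dtype=np.uint16
        )

    pre = background()
    pre[inj_mask] = lit(n_inj)

    post = background()
    truth: dict[str, float] = {}
    for name in sorted(fractions):
        mask = rois.masks[name]
        n_lit = int(round(fractions[name] * n_inj))
        if n_lit > int(mask.sum()):
            raise ConfigError(f"ROI '{name}' too small for requested fraction")
        idx = np.flatnonzero(mask.ravel())[:n_lit]
        flat = post.ravel()
        flat[idx] = lit(n_lit)
        truth[name] = n_lit / n_inj
    return (
        FluorescenceScan(pre, label="pre"),
        FluorescenceScan(post, label="post"),
        rois,
        truth,
    )


def _block_rois(shape: tuple[int, int], names: list[str]) -> RoiSet:
    """Disjoint rectangular ROIs tiling the image top-to-bottom."""
    h, w = shape
    k = len(names)
    rows = max(h // k, 1)
    masks = {}
    for i, name in enumerate(names):
        mask = np.zeros(shape, dtype=bool)
        r0 = i * rows
        r1 = h if i == k - 1 else (i + 1) * rows
        # pad one blank row between ROIs to keep them visually separate
        mask[r0 : max(r1 - 1, r0 + 1), 2 : w - 2] = True
        masks[name] = mask
    return RoiSet(masks=masks)
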