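"""Branching network geometry as per-branch piecewise-linear incline functions.

The simulation is intrinsically one-dimensional along the channel
centerline, so a network is encoded as junctions carrying a global
arc-length position ``x`` (m, from the injection start) and the local
incline angle there.  A branch is an ordered junction sequence with
strictly increasing ``x``; a non-root branch begins at the turn junction
it forks from, which guarantees continuity of the incline function when
a path switches branches.  Turns may additionally be annotated with the
arc positions of nearby untargeted ("parallel") channel mouths.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import NetworkValidationError, PathError

__all__ = [
    "Junction",
    "Network",
    "PathPlan",
    "Turn",
    "PathProfile",
    "validate_network",
    "find_path",
    "path_profile",
    "incline_at",
    "load_network",
    "save_network",
]

_KINDS = ("waypoint", "turn", "terminal")


@dataclass(frozen=True)
class Junction:
    """A labelled point along a channel centerline.

    ``x`` is arc length from the network start (m); ``parallel_offsets``
    are arc positions of adjacent untargeted channel mouths (m), relevant
    only at turns; ``children`` lists the branch ids forking here.
    """

    id: str
    x: float
    phi_deg: float
    kind: str = "waypoint"
    parallel_offsets: tuple[float, ...] = ()
    children: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise NetworkValidationError(
                [f"junction '{self.id}': unknown kind '{self.kind}'"]
            )


@dataclass(frozen=True)
class Network:
    """Junction set, branch topology, and the targeted branch."""

    junctions: dict[str, Junction]
    branches: dict[str, tuple[str, ...]]
    root: str
    target: str
    channel_diameter: float | None = None


@dataclass(frozen=True)
class PathPlan:
    """Branch sequence from the root to the target, with turn choices."""

    branches: tuple[str, ...]
    turns: tuple[tuple[str, str], ...]  # (turn junction id, chosen child branch)


@dataclass(frozen=True)
class Turn:
    """A turn event along a compiled path."""

    junction_id: str
    x: float
    parallel_offsets: tuple[float, ...]


@dataclass(frozen=True)
class PathProfile:
    """Compiled piecewise-linear incline function phi(x) along a path."""

    xs: np.ndarray
    phis: np.ndarray
    turns: tuple[Turn, ...]
    end_x: float


# ---------------------------------------------------------------------------
def validate_network(net: Network) -> list[str]:
    """Return a list of human-readable invariant violations (empty = valid)."""
    issues: list[str] = []
    referenced: set[str] = set()
    for bid, seq in net.branches.items():
        if not seq:
            issues.append(f"branch '{bid}' is empty")
            continue
        missing = [j for j in seq if j not in net.junctions]
        if missing:
            issues.append(f"branch '{bid}' references unknown junction(s) {missing}")
            continue
        referenced.update(seq)
        xs = [net.junctions[j].x for j in seq]
        if any(b <= a for a, b in zip(xs, xs[1:])):
            issues.append(
                f"monotonicity violation: branch '{bid}' arc positions "
                f"not strictly increasing"
            )
    for jid, j in net.junctions.items():
        if j.x < 0:
            issues.append(f"junction '{jid}' has negative arc position")
        if not -90.0 < j.phi_deg < 90.0:
            issues.append(f"junction '{jid}' incline angle out of (-90, 90) deg")
        if j.kind == "turn" and len(j.children) < 2:
            issues.append(f"turn junction '{jid}' has fewer than 2 children")
        if j.kind == "turn":
            unknown = [b for b in j.children if b not in net.branches]
            if unknown:
                issues.append(f"turn '{jid}' lists unknown child branch(es) {unknown}")
        if jid not in referenced:
            issues.append(f"orphan junction '{jid}' belongs to no branch")
    if net.root not in net.branches:
        issues.append(f"root branch '{net.root}' missing")
    if net.target not in net.branches:
        issues.append(f"missing target: branch '{net.target}' not in network")
    # each non-root branch must fork from exactly one turn junction
    child_of: dict[str, str] = {}
    for jid, j in net.junctions.items():
        for b in j.children:
            if b in child_of:
                issues.append(f"branch '{b}' forks from multiple turns")
            child_of[b] = jid
    for bid, seq in net.branches.items():
        if bid == net.root or not seq or seq[0] not in net.junctions:
            continue
        if bid not in child_of:
            issues.append(f"branch '{bid}' is unreachable (no parent turn)")
        elif seq[0] != child_of[bid]:
            issues.append(
                f"branch '{bid}' must begin at its parent turn junction "
                f"'{child_of[bid]}'"
            )
    if not issues and net.target != net.root:
        try:
            find_path(net, net.target)
        except PathError as exc:
            issues.append(str(exc))
    return issues


def check_network(net: Network) -> Network:
    """Raise :class:`NetworkValidationError` listing all violations, if any."""
    issues = validate_network(net)
    if issues:
        raise NetworkValidationError(issues)
    return net


# ---------------------------------------------------------------------------
def find_path(net: Network, target: str | None = None) -> PathPlan:
    """Depth-first search for the branch sequence from root to target."""
    target = net.target if target is None else target

    def dfs(bid: str, turns: list[tuple[str, str]],
            branches: list[str]) -> PathPlan | None:
        branches = branches + [bid]
        if bid == target:
            return PathPlan(branches=tuple(branches), turns=tuple(turns))
        seq = net.branches.get(bid, ())
        if not seq:
            return None
        last = net.junctions[seq[-1]]
        if last.kind != "turn":
            return None
        for child in last.children:
            found = dfs(child, turns + [(last.id, child)], branches)
            if found is not None:
                return found
        return None

    plan = dfs(net.root, [], [])
    if plan is None:
        raise PathError(f"target branch '{target}' unreachable from root")
    return plan


def path_profile(net: Network, plan: PathPlan | None = None) -> PathProfile:
    """Compile a path into interpolation arrays and its turn events."""
    if plan is None:
        plan = find_path(net)
    xs: list[float] = []
    phis: list[float] = []
    turns: list[Turn] = []
    for k, bid in enumerate(plan.branches):
        seq = net.branches[bid]
        last_on_path = (k == len(plan.branches) - 1)
        for jid in seq:
            j = net.junctions[jid]
            if xs and j.x == xs[-1]:
                continue  # shared turn junction between branches
            xs.append(j.x)
            phis.append(j.phi_deg)
        end_j = net.junctions[seq[-1]]
        if not last_on_path:
            turns.append(Turn(end_j.id, end_j.x, end_j.parallel_offsets))
    return PathProfile(
        xs=np.asarray(xs), phis=np.asarray(phis),
        turns=tuple(turns), end_x=float(xs[-1]),
    )


def incline_at(net: Network, plan: PathPlan, x) -> float | np.ndarray:
    """Incline angle (deg) at arc position x along a planned path.

    Linear interpolation between junction points; exact at junctions.
    """
    profile = path_profile(net, plan)
    return profile_incline_at(profile, x)


def profile_incline_at(profile: PathProfile, x):
    """As :func:`incline_at` but on a pre-compiled profile (fast path)."""
    x_arr = np.asarray(x, dtype=float)
    if np.any((x_arr < profile.xs[0]) | (x_arr > profile.end_x)):
        raise PathError(
            f"position outside path range [{profile.xs[0]}, {profile.end_x}] m"
        )
    out = np.interp(x_arr, profile.xs, profile.phis)
    return out if out.ndim else float(out)


# ------------------------------- IO ----------------------------------------
def _net_to_dict(net: Network) -> dict:
    return {
        "junctions": [
            {
                "id": j.id,
                "x_mm": j.x / 1e-3,
                "phi_deg": j.phi_deg,
                "kind": j.kind,
                "children": list(j.children),
                "parallel_offsets_mm": [p / 1e-3 for p in j.parallel_offsets],
            }
            for j in net.junctions.values()
        ],
        "branches": {bid: list(seq) for bid, seq in net.branches.items()},
        "root": net.root,
        "target": net.target,
        "channel_diameter_mm": (
            None if net.channel_diameter is None else net.channel_diameter / 1e-3
        ),
    }


def _net_from_dict(d: dict) -> Network:
    junctions = {
        row["id"]: Junction(
            id=row["id"],
            x=row["x_mm"] * 1e-3,
            phi_deg=row["phi_deg"],
            kind=row.get("kind", "waypoint"),
            children=tuple(row.get("children", ())),
            parallel_offsets=tuple(
                p * 1e-3 for p in row.get("parallel_offsets_mm", ())
            ),
        )
        for row in d["junctions"]
    }
    diam = d.get("channel_diameter_mm")
    return Network(
        junctions=junctions,
        branches={bid: tuple(seq) for bid, seq in d["branches"].items()},
        root=d["root"],
        target=d["target"],
        channel_diameter=None if diam is None else diam * 1e-3,
    )


def save_network(net: Network, path: str | Path) -> None:
    """Write a network to JSON (default) or flat CSV by file extension."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        _save_csv(net, path)
    else:
        path.write_text(json.dumps(_net_to_dict(net), indent=2))


def load_network(path: str | Path, validate: bool = True) -> Network:
    """Read a network from JSON or flat CSV; validates by default."""
    path = Path(path)
    net = (
        _load_csv(path)
        if path.suffix.lower() == ".csv"
        else _net_from_dict(json.loads(path.read_text()))
    )
    return check_network(net) if validate else net


_CSV_FIELDS = [
    "branch", "order", "id", "x_mm", "phi_deg", "kind", "children",
    "parallel_offsets_mm", "root", "target", "channel_diameter_mm",
]


def _save_csv(net: Network, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
        w.writeheader()
        first = True
        for bid, seq in net.branches.items():
            for order, jid in enumerate(seq):
                j = net.junctions[jid]
                row = {
                    "branch": bid, "order": order, "id": jid,
                    "x_mm": repr(j.x / 1e-3), "phi_deg": repr(j.phi_deg),
                    "kind": j.kind, "children": ";".join(j.children),
                    "parallel_offsets_mm": ";".join(
                        repr(p / 1e-3) for p in j.parallel_offsets
                    ),
                }
                if first:
                    row.update(
                        root=net.root, target=net.target,
                        channel_diameter_mm=(
                            "" if net.channel_diameter is None
                            else repr(net.channel_diameter / 1e-3)
                        ),
                    )
                    first = False
                w.writerow(row)


def _load_csv(path: Path) -> Network:
    junctions: dict[str, Junction] = {}
    branches: dict[str, list[str]] = {}
    root = target = None
    diam = None
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "branch" not in reader.fieldnames:
            raise NetworkValidationError(["CSV missing required header"])
        for row in reader:
            jid = row["id"]
            if jid not in junctions:
                junctions[jid] = Junction(
                    id=jid,
                    x=float(row["x_mm"]) * 1e-3,
                    phi_deg=float(row["phi_deg"]),
                    kind=row["kind"],
                    children=tuple(c for c in row["children"].split(";") if c),
                    parallel_offsets=tuple(
                        float(p) * 1e-3
                        for p in row["parallel_offsets_mm"].split(";") if p
                    ),
                )
            branches.setdefault(row["branch"], []).append(jid)
            if row.get("root"):
                root, target = row["root"], row["target"]
                if row.get("channel_diameter_mm"):
                    diam = float(row["channel_diameter_mm"]) * 1e-3
    if root is None or target is None:
        raise NetworkValidationError(["CSV missing root/target annotation"])
    return Network(
        junctions=junctions,
        branches={b: tuple(seq) for b, seq in branches.items()},
        root=root, target=target, channel_diameter=diam,
    )
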