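"""Slice-interleaved diffusion encoding (SIDE) scheme planning.

In SIDE, each simultaneous multi-slice (SMS) excitation covers one *slice
group* of ``r_sms`` slices, and ``n_sg = n_slices / r_sms`` groups cover the
volume. A conventional acquisition gives every slice group of a volume the
same wavevector; SIDE instead assigns a different wavevector to each group,
so that one volume samples ``n_sg`` wavevectors at once. ``n_q / n_sg``
volumes form a *cycle* covering every wavevector once (one slice group
each); the assignment is shifted by one group per cycle, and ``n_sg`` cycles
cover every (wavevector, slice group) pair exactly once. Skipping cycles
undersamples by ``r_side``; combined with SMS the total acceleration is
``r_sms * r_side``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np


class SchemeError(ValueError):
    """Invalid scheme sizes (divisibility violations and the like)."""


@dataclass(frozen=True)
class SliceGrouping:
    """Partition of ``n_slices`` slices into ``n_sg`` SMS slice groups.

    Group g contains the evenly spaced slices ``{g + j*n_sg}``, one from
    each of the r_sms bands of the volume, matching how SMS excitation
    spreads its slices.
    """

    n_slices: int
    r_sms: int

    def __post_init__(self) -> None:
        if self.n_slices < 1 or self.r_sms < 1:
            raise SchemeError("n_slices and r_sms must be positive")
        if self.n_slices % self.r_sms:
            raise SchemeError(
                f"r_sms={self.r_sms} does not divide n_slices={self.n_slices}"
            )

    @property
    def n_sg(self) -> int:
        return self.n_slices // self.r_sms

    def group_slices(self, g: int) -> np.ndarray:
        """Slice indices of group g: g, g+n_sg, ..., g+(r_sms-1)*n_sg."""
        if not 0 <= g < self.n_sg:
            raise SchemeError(f"slice group {g} out of range [0, {self.n_sg})")
        return g + self.n_sg * np.arange(self.r_sms)

    @property
    def sg_slices(self) -> np.ndarray:
        """(n_sg, r_sms) table of slice indices per group."""
        return np.arange(self.n_sg)[:, None] + self.n_sg * np.arange(self.r_sms)

    def slice_to_group(self) -> np.ndarray:
        """(n_slices,) map from slice index to its group."""
        out = np.empty(self.n_slices, dtype=int)
        for g in range(self.n_sg):
            out[self.group_slices(g)] = g
        return out


@dataclass(frozen=True)
class SideScheme:
    """A full SIDE schedule plus its acquired-cycle subset.

    ``assignment(c, m, g) = m*n_sg + (g + c) % n_sg`` maps (cycle c, volume
    m within the cycle, slice group g) to a wavevector index: within one
    cycle every wavevector appears exactly once, and the +1 modular shift
    per cycle makes every (wavevector, slice group) pair appear exactly once
    over all ``n_sg`` cycles. Acquired cycles are evenly spaced starting at
    cycle 0.
    """

    grouping: SliceGrouping
    n_q: int
    r_side: int

    def __post_init__(self) -> None:
        n_sg = self.grouping.n_sg
        if self.n_q % n_sg:
            raise SchemeError(f"n_sg={n_sg} does not divide n_q={self.n_q}")
        if self.r_side < 1 or n_sg % self.r_side:
            raise SchemeError(
                f"r_side={self.r_side} does not divide n_sg={n_sg}"
            )

    @property
    def n_sg(self) -> int:
        return self.grouping.n_sg

    @property
    def volumes_per_cycle(self) -> int:
        return self.n_q // self.n_sg

    @property
    def n_cycles_total(self) -> int:
        return self.n_sg

    @property
    def acquired_cycles(self) -> np.ndarray:
        return np.arange(0, self.n_sg, self.r_side)

    @property
    def n_acquired_volumes(self) -> int:
        return self.n_q // self.r_side

    def assignment(self, cycle: int, volume: int, group: int) -> int:
        """Wavevector carried by slice group ``group`` of volume ``volume``
        in cycle ``cycle``."""
        n_sg = self.n_sg
        if not (0 <= cycle < n_sg and 0 <= volume < self.volumes_per_cycle
                and 0 <= group < n_sg):
            raise SchemeError("assignment index out of range")
        return volume * n_sg + (group + cycle) % n_sg

    def assignment_table(self) -> np.ndarray:
        """(n_cycles, volumes_per_cycle, n_sg) wavevector indices."""
        n_sg = self.n_sg
        c = np.arange(n_sg)[:, None, None]
        m = np.arange(self.volumes_per_cycle)[None, :, None]
        g = np.arange(n_sg)[None, None, :]
        return m * n_sg + (g + c) % n_sg

    def acquired_pairs(self) -> np.ndarray:
        """(n_q, n_sg) boolean: acquired (wavevector, slice group) pairs."""
        mask = np.zeros((self.n_q, self.n_sg), dtype=bool)
        table = self.assignment_table()
        for c in self.acquired_cycles:
            for g in range(self.n_sg):
                mask[table[c, :, g], g] = True
        return mask

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_slices": self.grouping.n_slices,
                "r_sms": self.grouping.r_sms,
                "n_q": self.n_q,
                "r_side": self.r_side,
                "n_sg": self.n_sg,
                "volumes_per_cycle": self.volumes_per_cycle,
                "acquired_cycles": self.acquired_cycles.tolist(),
                "assignment": self.assignment_table().tolist(),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "SideScheme":
        d = json.loads(text)
        return cls(SliceGrouping(d["n_slices"], d["r_sms"]), d["n_q"], d["r_side"])


def make_grouping(n_slices: int, r_sms: int) -> SliceGrouping:
    """Partition ``n_slices`` into SMS groups of evenly spaced slices."""
    return SliceGrouping(n_slices, r_sms)


def plan_side(grouping: SliceGrouping, n_q: int, r_side: int = 1) -> SideScheme:
    """Plan the SIDE cycle/offset schedule with undersampling ``r_side``."""
    return SideScheme(grouping, n_q, r_side)


def total_acceleration(scheme: SideScheme) -> int:
    """Total undersampling factor r_sms * r_side."""
    return scheme.grouping.r_sms * scheme.r_side


def allocate_per_shell(shell_sizes, r: int) -> list[int]:
    """Largest-remainder proportional allocation of ``total/r`` directions.

    Remainder ties are resolved toward larger shells.
    """
    sizes = [int(s) for s in shell_sizes]
    total = sum(sizes)
    if r < 1:
        raise SchemeError("undersampling factor must be >= 1")
    if total % r:
        raise SchemeError(f"r={r} does not divide the {total} directions")
    budget = total // r
    quotas = [s * budget / total for s in sizes]
    alloc = [int(np.floor(q)) for q in quotas]
    remainders = [q - a for q, a in zip(quotas, alloc)]
    # hand out leftover slots by descending remainder, larger shells first on ties
    order = sorted(range(len(sizes)), key=lambda i: (-remainders[i], -sizes[i]))
    for i in order[: budget - sum(alloc)]:
        alloc[i] += 1
    return alloc


def _greedy_farthest(points: np.ndarray, k: int) -> np.ndarray:
    """Greedy farthest-point subset of antipodally symmetric directions.

    Distance is the acute angle between axes; the seed is the first point.
    """
    n = points.shape[0]
    if k >= n:
        return np.arange(n)
    cos = np.abs(points @ points.T).clip(0, 1)
    chosen = [0]
    mindist = np.arccos(cos[0])
    for _ in range(1, k):
        nxt = int(np.argmax(mindist))
        chosen.append(nxt)
        mindist = np.minimum(mindist, np.arccos(cos[nxt]))
    return np.array(sorted(chosen))


def plan_conventional(shell_sizes, r: int, directions: np.ndarray | None = None) -> np.ndarray:
    """Select wavevector indices for conventional (angular) undersampling.

    Keeps ``total/r`` directions, allocated per shell by largest-remainder
    proportional rounding; within a shell, retained directions maximize
    angular spread (greedy farthest-point) when ``directions`` for the
    concatenated shells are given, otherwise they are taken evenly spaced.
    Returns indices into the concatenated shell ordering.
    """
    sizes = [int(s) for s in shell_sizes]
    alloc = allocate_per_shell(sizes, r)
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    selected: list[np.ndarray] = []
    for i, (size, keep) in enumerate(zip(sizes, alloc)):
        idx = np.arange(offsets[i], offsets[i] + size)
        if keep == size:
            selected.append(idx)
        elif directions is not None:
            sub = _greedy_farthest(np.asarray(directions, dtype=float)[idx], keep)
            selected.append(idx[sub])
        else:
            stride = np.linspace(0, size - 1, keep).round().astype(int)
            selected.append(idx[np.unique(stride)])
    return np.concatenate(selected)
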