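"""Assembly of crosspeaks into spin systems and overlap groups.

A spin system is the set of crosspeaks rooted at one backbone amide H-N pair.
Peaks join a growing spin system when their amide shifts (the two dimensions
of unambiguous type shared by every experiment here) match within tolerance.
A peak whose amide matches but whose carbon shift clashes with every
established resonance spawns a *sibling* spin system in the same overlap
group: the group marks amide-degenerate spin systems whose carbon peaks may be
exchanged during annealing.

A resonance type set is one internally consistent labeling of every ambiguous
peak dimension as an (i) or (i-1) resonance; a spin system with only
unambiguous peaks has exactly one.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from .io import CrossPeak
from .spectra import ALL_LABELS, DEFAULT_TOLERANCES, nucleus_of

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ResonanceTypeSet:
    """One consistent assignment of every peak dimension to a resonance label.

    ``labels[j]`` is the resonance-type tuple chosen for the j-th peak of the
    owning spin system; ``mean_shifts`` maps each label present to the
    arithmetic mean (ppm) of all contributing peak dimensions.
    """

    labels: tuple[tuple[str, ...], ...]
    mean_shifts: dict[str, float] = field(compare=False, hash=False, default_factory=dict)


class SpinSystem:
    """A set of crosspeaks sharing one amide, with its resonance type sets."""

    _counter = itertools.count(1)

    def __init__(self, peaks: list[CrossPeak], uid: str | None = None):
        self.uid = uid or f"SS{next(SpinSystem._counter)}"
        self.peaks: list[CrossPeak] = list(peaks)
        self.group: "SpinSystemGroup | None" = None
        self.type_sets: list[ResonanceTypeSet] = []
        self.version = 0  # bumped whenever peak membership changes
        self._pcache = None  # posterior-matrix cache, managed by energy module

    # -- amide root ---------------------------------------------------------
    @property
    def amide_h(self) -> float:
        return sum(p.amide_shifts[0] for p in self.peaks) / len(self.peaks)

    @property
    def amide_n(self) -> float:
        return sum(p.amide_shifts[1] for p in self.peaks) / len(self.peaks)

    @property
    def n_type_sets(self) -> int:
        return len(self.type_sets)

    def touch(self) -> None:
        """Invalidate caches after a peak-membership change."""
        self.version += 1
        self._pcache = None

    def refresh_type_sets(self, tolerances: dict[str, float]) -> None:
        self.type_sets = enumerate_type_sets(self, tolerances)

    def clone(self) -> "SpinSystem":
        c = SpinSystem(self.peaks, uid=self.uid)
        c.type_sets = list(self.type_sets)
        c.version = self.version
        return c

    def __repr__(self):
        return f"<SpinSystem {self.uid}: {len(self.peaks)} peaks, I={len(self.type_sets)}>"


@dataclass
class SpinSystemGroup:
    """Spin systems sharing a degenerate amide; singleton for a unique amide."""

    members: list[SpinSystem] = field(default_factory=list)
    exchangeable_peaks: list[CrossPeak] = field(default_factory=list)

    def add(self, ss: SpinSystem) -> None:
        ss.group = self
        self.members.append(ss)

    def clone(self) -> "SpinSystemGroup":
        g = SpinSystemGroup()
        for ss in self.members:
            g.add(ss.clone())
        g.exchangeable_peaks = list(self.exchangeable_peaks)
        return g


# ---------------------------------------------------------------------------
# type-set enumeration


_LABEL_NUCLEUS = {label: nucleus_of(label) for label in ALL_LABELS}


def _tolerance_of(label: str, tolerances: dict[str, float]) -> float:
    return tolerances[_LABEL_NUCLEUS[label]]


def _enumerate(peaks, tolerances, first_only=False):
    """DFS over per-peak candidate types keeping per-label running means.

    A candidate is consistent when, for each of its labels, the peak's shift
    lies within the label's nucleus tolerance of the running mean established
    by previously assigned peaks.
    """
    tol = {label: tolerances[_LABEL_NUCLEUS[label]] for label in ALL_LABELS}
    # visiting peaks with fewer candidates first prunes earlier
    order = sorted(range(len(peaks)), key=lambda j: len(peaks[j].spectrum.candidate_peak_types))
    results: list[tuple[tuple[str, ...], ...]] = []
    chosen: list[tuple[str, ...]] = [None] * len(peaks)  # type: ignore[list-item]
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}

    def rec(k: int) -> bool:
        if k == len(order):
            results.append(tuple(chosen))
            return first_only
        j = order[k]
        peak = peaks[j]
        for cand in peak.spectrum.candidate_peak_types:
            ok = True
            touched = []
            for label, shift in zip(cand, peak.shifts):
                cnt = counts.get(label, 0)
                if cnt:
                    mean = sums[label] / cnt
                    if abs(shift - mean) > tol[label]:
                        ok = False
                        break
                sums[label] = sums.get(label, 0.0) + shift
                counts[label] = cnt + 1
                touched.append((label, shift))
            if ok:
                chosen[j] = cand
                if rec(k + 1):
                    return True
            for label, shift in touched:
                sums[label] -= shift
                counts[label] -= 1
            # fully undone; try next candidate
        return False

    rec(0)
    return results


def _mean_shift_map(peaks, labels) -> dict[str, float]:
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for peak, cand in zip(peaks, labels):
        for label, shift in zip(cand, peak.shifts):
            sums[label] = sums.get(label, 0.0) + shift
            counts[label] = counts.get(label, 0) + 1
    return {label: sums[label] / counts[label] for label in sums}


def enumerate_type_sets(
    ss: SpinSystem | list[CrossPeak], tolerances: dict[str, float] | None = None
) -> list[ResonanceTypeSet]:
    """Exhaustive, duplicate-free list of consistent resonance type sets."""
    peaks = ss.peaks if isinstance(ss, SpinSystem) else ss
    tol = {**DEFAULT_TOLERANCES, **(tolerances or {})}
    labelings = _enumerate(peaks, tol)
    return [ResonanceTypeSet(lab, _mean_shift_map(peaks, lab)) for lab in labelings]


def is_consistent(peaks: list[CrossPeak], tolerances: dict[str, float]) -> bool:
    """True when at least one consistent resonance type set exists."""
    return bool(_enumerate(peaks, tolerances, first_only=True))


def mean_shifts(ss: SpinSystem, ts: ResonanceTypeSet) -> dict[str, float]:
    """Arithmetic-mean shift per resonance label for one type set."""
    return _mean_shift_map(ss.peaks, ts.labels)


# ---------------------------------------------------------------------------
# spin-system assembly


def _amide_matches(peak: CrossPeak, ss: SpinSystem, tol: dict[str, float]) -> bool:
    h, n = peak.amide_shifts
    return abs(h - ss.amide_h) <= tol["H"] and abs(n - ss.amide_n) <= tol["N"]


def _narrow_candidates(ss: SpinSystem) -> None:
    """Record per-peak resolved types implied by the surviving type sets."""
    if not ss.type_sets:
        return
    for j, peak in enumerate(ss.peaks):
        viable = tuple(dict.fromkeys(ts.labels[j] for ts in ss.type_sets))
        peak.candidates = viable


def assemble_spin_systems(
    peaks: list[CrossPeak],
    tolerances: dict[str, float] | None = None,
    cache_low_intensity: bool = False,
) -> list[SpinSystemGroup]:
    """Partition crosspeaks into spin systems grouped by amide degeneracy.

    The first unconsumed peak (input order) seeds each spin system; any
    remaining peak whose amide H and N shifts match the growing system within
    tolerance is added if it admits at least one consistent resonance type
    set, and otherwise spawns a sibling spin system in the same group.
    Deterministic for a fixed input order.

    When ``cache_low_intensity`` is set, peaks in the lowest 5% of intensity
    within their spectrum's list are flagged as eligible for the crosspeak
    cache during annealing.
    """
    if not peaks:
        raise ValueError("no peaks to assemble")
    tol = {**DEFAULT_TOLERANCES, **(tolerances or {})}

    if cache_low_intensity:
        _flag_low_intensity(peaks)

    remaining = list(peaks)
    groups: list[SpinSystemGroup] = []
    while remaining:
        seed = remaining.pop(0)
        group = SpinSystemGroup()
        group.add(SpinSystem([seed]))
        changed = True
        while changed:
            changed = False
            keep = []
            for p in remaining:
                amide_ok = False
                placed = False
                for member in group.members:
                    if not _amide_matches(p, member, tol):
                        continue
                    amide_ok = True
                    if is_consistent(member.peaks + [p], tol):
                        member.peaks.append(p)
                        member.touch()
                        placed = True
                        break
                if not placed and amide_ok:
                    # clash with every sibling: new spin system, same group
                    group.add(SpinSystem([p]))
                    placed = True
                if placed:
                    changed = True
                else:
                    keep.append(p)
            remaining = keep
        for member in group.members:
            member.refresh_type_sets(tol)
            _narrow_candidates(member)
            if not member.type_sets:  # single inconsistent peak cannot occur,
                logger.warning("spin system %s has no consistent type set", member.uid)
        if len(group.members) > 1:
            group.exchangeable_peaks = [
                p
                for ss in group.members
                for p in ss.peaks
                if p.spectrum.carbon_dims
            ]
            logger.debug(
                "degenerate amide group with %d spin systems, %d exchangeable peaks",
                len(group.members),
                len(group.exchangeable_peaks),
            )
        groups.append(group)
    # deterministic uids independent of prior assemblies in the process
    for k, ss in enumerate((m for g in groups for m in g.members), start=1):
        ss.uid = f"SS{k}"
    return groups


def _flag_low_intensity(peaks: list[CrossPeak]) -> None:
    by_spectrum: dict[str, list[CrossPeak]] = {}
    for p in peaks:
        by_spectrum.setdefault(p.spectrum.name, []).append(p)
    for plist in by_spectrum.values():
        with_int = [p for p in plist if p.intensity is not None]
        if len(with_int) < 2:
            continue
        ordered = sorted(with_int, key=lambda p: abs(p.intensity))
        cutoff = max(1, int(0.05 * len(ordered)))
        threshold = abs(ordered[cutoff - 1].intensity)
        for p in with_int:
            p.cache_eligible = abs(p.intensity) <= threshold


def all_spin_systems(groups: list[SpinSystemGroup]) -> list[SpinSystem]:
    return [ss for g in groups for ss in g.members]
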