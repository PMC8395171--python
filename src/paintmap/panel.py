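"""Sequential-FISH panel planning.

Chromosomes are identified by the combination of probes that light them
up across rounds (their barcode), optionally refined by differing signal
morphologies (window-density patterns) within a barcode-sharing group,
and at most one chromosome may be named by exclusion once all others are
positively identified. Two fluorophores are available per round; probes
are never reused across rounds because re-probing strips prior signal.

Plan verification uses confident-level calls by default: counts in the
uncertain band have produced no observable signal under the microscope
often enough that they cannot anchor a positive identification.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .signals import SignalCall, _LEVEL_RANK, pattern_distance

FLUOROPHORES = ("digoxigenin-red", "biotin-green")


@dataclass(frozen=True)
class PlanConstraints:
    """Experimental constraints on a sequential-FISH identification plan.

    extra_probes maps single-locus probes (e.g. rDNA markers) to the one
    chromosome they land on; such probes can share a round and fluorophore
    with a painting probe because a single dot is visually distinct from a
    paint. signal_level is the minimum call level that counts as a positive
    signal in barcodes ("present" by default; "uncertain" would trust the
    candidate band).
    """

    fluorophores_per_round: int = 2
    max_rounds: int = 5
    allow_exclusion: bool = True
    allow_pattern_disambiguation: bool = True
    extra_probes: dict[str, str] = field(default_factory=dict)
    signal_level: str = "present"
    pattern_tv_threshold: float = 0.2

    def __post_init__(self) -> None:
        if self.fluorophores_per_round < 1:
            raise ValueError("fluorophores_per_round must be >= 1")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")
        if self.signal_level not in _LEVEL_RANK:
            raise ValueError(f"unknown signal_level {self.signal_level!r}")

    @property
    def paint_capacity(self) -> int:
        return self.fluorophores_per_round * self.max_rounds


@dataclass
class FISHPanelPlan:
    """Ordered probing rounds plus the chromosome identification map.

    rounds hold (probe, fluorophore) pairs; id_map records, per chromosome,
    the evidence that names it ("barcode:...", "pattern:...", "extra:..."
    or "by exclusion") once the plan has been verified.
    """

    rounds: list[list[tuple[str, str]]]
    id_map: dict[str, str] = field(default_factory=dict)
    resolved: bool = False

    @property
    def all_probes(self) -> list[str]:
        return [p for rnd in self.rounds for p, _ in rnd]

    def paint_probes_under(self, constraints: "PlanConstraints") -> list[str]:
        """Painting probes in round order; single-locus extras excluded."""
        return [p for p in self.all_probes if p not in constraints.extra_probes]

    @property
    def n_rounds(self) -> int:
        return len(self.rounds)

    def to_dict(self) -> dict:
        return {
            "rounds": [[list(pair) for pair in rnd] for rnd in self.rounds],
            "id_map": dict(sorted(self.id_map.items())),
            "resolved": self.resolved,
        }


class PlanError(ValueError):
    pass


def _resolve(
    probes: list[str], calls: SignalCall, constraints: PlanConstraints
) -> tuple[dict[str, str], set[str]]:
    """Core identification logic shared by verify/plan/enumerate.

    Returns (id_map for resolved chromosomes, unresolved set). ``probes``
    are painting probes; constraints.extra_probes always participate.
    """
    rank = _LEVEL_RANK[constraints.signal_level]
    chroms = calls.chromosomes
    extra_names = sorted(constraints.extra_probes)
    for chrom in constraints.extra_probes.values():
        if chrom not in chroms:
            raise PlanError(f"extra probe targets unknown chromosome {chrom!r}")

    def barcode(chrom: str) -> tuple[int, ...]:
        paint = tuple(
            1 if _LEVEL_RANK[calls.level(p, chrom)] >= rank else 0 for p in probes
        )
        extra = tuple(
            1 if constraints.extra_probes[name] == chrom else 0 for name in extra_names
        )
        return paint + extra

    groups: dict[tuple[int, ...], list[str]] = {}
    codes = {}
    for chrom in chroms:
        code = barcode(chrom)
        codes[chrom] = code
        groups.setdefault(code, []).append(chrom)

    id_map: dict[str, str] = {}
    unresolved: set[str] = set()
    n_probes = len(probes) + len(extra_names)
    zero_code = tuple([0] * n_probes)

    for code, members in groups.items():
        if code == zero_code:
            unresolved.update(members)
            continue
        if len(members) == 1:
            chrom = members[0]
            lit = [p for p, bit in zip(list(probes) + extra_names, code) if bit]
            id_map[chrom] = "barcode:" + "+".join(lit)
            continue
        if not constraints.allow_pattern_disambiguation:
            unresolved.update(members)
            continue
        # pattern refinement: a member is resolved when its morphology differs
        # from every other member's on some shared lit probe
        for chrom in members:
            distinct_from_all = True
            for other in members:
                if other == chrom:
                    continue
                separable = False
                for p in probes:
                    a = calls.patterns.get((p, chrom))
                    b = calls.patterns.get((p, other))
                    if a is not None and b is not None:
                        if pattern_distance(a, b) > constraints.pattern_tv_threshold:
                            separable = True
                            break
                if not separable:
                    distinct_from_all = False
                    break
            if distinct_from_all:
                lit = [p for p, bit in zip(list(probes) + extra_names, code) if bit]
                id_map[chrom] = "pattern:" + "+".join(lit)
            else:
                unresolved.add(chrom)

    if constraints.allow_exclusion and len(unresolved) == 1:
        leftover = next(iter(unresolved))
        id_map[leftover] = "by exclusion"
        unresolved = set()
    return id_map, unresolved


def verify_plan(
    plan: FISHPanelPlan, calls: SignalCall, constraints: PlanConstraints
) -> tuple[bool, set[str]]:
    """Check whether a plan identifies every chromosome.

    Fills plan.id_map and plan.resolved as a side effect and returns
    (resolved, unresolved chromosomes).
    """
    probes = plan.paint_probes_under(constraints)
    missing = [p for p in probes if p not in calls.probe_sets]
    if missing:
        raise PlanError(f"planned probes missing from signal calls: {missing}")
    if len(set(probes)) != len(probes):
        raise PlanError("probes must not be reused across rounds")
    for rnd in plan.rounds:
        fluors = {f for _, f in rnd}
        if len(fluors) > constraints.fluorophores_per_round:
            raise PlanError(
                f"round {rnd} uses {len(fluors)} fluorophores "
                f"(max {constraints.fluorophores_per_round})"
            )
    id_map, unresolved = _resolve(probes, calls, constraints)
    plan.id_map = id_map
    plan.resolved = not unresolved
    return plan.resolved, unresolved


def _pack_rounds(probes: list[str], constraints: PlanConstraints) -> list[list[tuple[str, str]]]:
    """Pack probes into rounds in selection order, one fluorophore each."""
    per_round = constraints.fluorophores_per_round
    rounds = [
        [
            (p, FLUOROPHORES[j % len(FLUOROPHORES)])
            for j, p in enumerate(probes[i : i + per_round])
        ]
        for i in range(0, len(probes), per_round)
    ]
    extras = [
        (name, FLUOROPHORES[i % len(FLUOROPHORES)])
        for i, name in enumerate(sorted(constraints.extra_probes))
    ]
    if extras:
        # single-locus markers ride along in the final round
        if rounds:
            rounds[-1].extend(extras)
        else:
            rounds = [extras]
    return rounds


def plan_rounds(
    calls: SignalCall, constraints: PlanConstraints | None = None
) -> FISHPanelPlan:
    """Greedy probe selection packed into sequential rounds.

    Repeatedly adds the probe resolving the most additional chromosomes
    (ties: smaller candidate set, then label order); keeps adding while
    capacity remains even at zero marginal gain, since a later probe may
    only discriminate jointly. Returns a verified plan, or the best
    partial plan with resolved=False.
    """
    constraints = constraints or PlanConstraints()
    available = list(calls.probe_sets)
    if not available:
        raise PlanError("no probes available")
    chosen: list[str] = []
    _, unresolved = _resolve(chosen, calls, constraints)
    while unresolved and len(chosen) < constraints.paint_capacity:
        remaining = [p for p in available if p not in chosen]
        if not remaining:
            break
        best, best_key = None, None
        current_resolved = len(calls.chromosomes) - len(unresolved)
        for p in remaining:
            _, unres_p = _resolve(chosen + [p], calls, constraints)
            gain = (len(calls.chromosomes) - len(unres_p)) - current_resolved
            key = (-gain, len(calls.candidate_set(p)), p)
            if best_key is None or key < best_key:
                best, best_key = p, key
        chosen.append(best)
        _, unresolved = _resolve(chosen, calls, constraints)
    plan = FISHPanelPlan(rounds=_pack_rounds(chosen, constraints))
    verify_plan(plan, calls, constraints)
    return plan


def enumerate_optimal(
    calls: SignalCall,
    constraints: PlanConstraints | None = None,
    max_probes: int | None = None,
) -> list[list[str]]:
    """All minimum-size resolving probe subsets, by exhaustive search.

    Intended as a small-instance oracle; guarded to <= 12 probes and <= 12
    chromosomes. Returns [] when no subset within max_probes resolves.
    """
    constraints = constraints or PlanConstraints()
    probes = list(calls.probe_sets)
    if len(probes) > 12 or len(calls.chromosomes) > 12:
        raise PlanError(
            f"instance too large for exhaustive search "
            f"({len(probes)} probes x {len(calls.chromosomes)} chromosomes, max 12x12)"
        )
    if max_probes is None:
        max_probes = min(len(probes), constraints.paint_capacity)
    for size in range(0, max_probes + 1):
        found = [
            list(subset)
            for subset in itertools.combinations(probes, size)
            if not _resolve(list(subset), calls, constraints)[1]
        ]
        if found:
            return found
    return []
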