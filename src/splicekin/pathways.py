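"""Two-channel coincidence matching and pathway classification.

Simultaneous arrival of a U4 and a U5 spot at the same molecule marks a
tri-snRNP binding event.  Each matched pair is then classified by how
the two spots disappear: U4 first (activation), U5 first, simultaneous
loss (intact tri-snRNP discard), or persistence to the end of the
recording.  Further analyses cover repeat binding, U4 reappearance
(rebinding) while U5 persists, the ordering of NTC arrival versus U4
release with a shuffled control, dwell-time correlations, and
nonspecific background binding rates.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .detect import EventInterval

__all__ = [
    "Outcome",
    "CoincidenceEvent",
    "PathwayTally",
    "OrderingRecord",
    "RebindingResult",
    "BackgroundRate",
    "match_coincident",
    "classify_outcomes",
    "multi_binding_summary",
    "rebinding_analysis",
    "ordering_offsets",
    "randomized_control",
    "dwell_correlation",
    "background_rate",
]


class Outcome(str, enum.Enum):
    U4_FIRST = "U4_FIRST"
    U5_FIRST = "U5_FIRST"
    SIMULTANEOUS_LOSS = "SIMULTANEOUS_LOSS"
    PERSIST = "PERSIST"


@dataclass
class CoincidenceEvent:
    """A matched simultaneous U4 + U5 arrival with its outcome route."""

    molecule_id: int
    t_arrival: float
    u4: EventInterval
    u5: EventInterval
    outcome: Outcome | None = None


@dataclass
class PathwayTally:
    counts: dict[str, int]
    total: int
    percentages: dict[str, float] = field(init=False)

    def __post_init__(self):
        if sum(self.counts.values()) != self.total:
            raise ValueError("route counts must sum to total")
        self.percentages = {
            k: round(100.0 * v / self.total, 1) if self.total else 0.0
            for k, v in self.counts.items()}


def match_coincident(events_a: Sequence[EventInterval],
                     events_b: Sequence[EventInterval],
                     tolerance_s: float = 3.0
                     ) -> tuple[list[CoincidenceEvent],
                                list[EventInterval], list[EventInterval]]:
    """Pair events across two channels by simultaneous arrival.

    Greedy nearest-start pairing within ``tolerance_s`` (default one
    frame spacing), per molecule; each interval is used at most once.
    Returns (pairs, unmatched_a, unmatched_b).
    """
    by_mol_a: dict[int, list[EventInterval]] = {}
    by_mol_b: dict[int, list[EventInterval]] = {}
    for ev in events_a:
        by_mol_a.setdefault(ev.molecule_id, []).append(ev)
    for ev in events_b:
        by_mol_b.setdefault(ev.molecule_id, []).append(ev)

    pairs, only_a, only_b = [], [], []
    for mol in sorted(set(by_mol_a) | set(by_mol_b)):
        evs_a = sorted(by_mol_a.get(mol, []), key=lambda e: e.t_start)
        evs_b = sorted(by_mol_b.get(mol, []), key=lambda e: e.t_start)
        used_b = [False] * len(evs_b)
        # candidate pairs ordered by |start offset|, ties by stream order
        cands = sorted(
            ((abs(a.t_start - b.t_start), ia, ib)
             for ia, a in enumerate(evs_a) for ib, b in enumerate(evs_b)
             if abs(a.t_start - b.t_start) <= tolerance_s),
            key=lambda c: (c[0], c[1], c[2]))
        used_a = [False] * len(evs_a)
        for _, ia, ib in cands:
            if used_a[ia] or used_b[ib]:
                continue
            used_a[ia] = used_b[ib] = True
            a, b = evs_a[ia], evs_b[ib]
            # assign the u4/u5 slots by channel label when present;
            # otherwise the first stream fills the u4 slot
            if b.channel == "U4" and a.channel != "U4":
                a, b = b, a
            pairs.append(CoincidenceEvent(
                mol, 0.5 * (a.t_start + b.t_start), a, b))
        only_a.extend(a for ia, a in enumerate(evs_a) if not used_a[ia])
        only_b.extend(b for ib, b in enumerate(evs_b) if not used_b[ib])
    pairs.sort(key=lambda p: (p.molecule_id, p.t_arrival))
    return pairs, only_a, only_b


def classify_outcomes(pairs: Iterable[CoincidenceEvent],
                      tolerance_s: float = 3.0) -> PathwayTally:
    """Assign an outcome route to every matched pair and tally them.

    PERSIST if both spots are censored at the end of the recording;
    SIMULTANEOUS_LOSS if both end uncensored within the tolerance; else
    U4_FIRST / U5_FIRST by the earlier departure (a censored partner
    counts as departing last).  Outcomes are stored on the pairs.
    """
    counts = {o.value: 0 for o in Outcome}
    total = 0
    for pair in pairs:
        u4, u5 = pair.u4, pair.u5
        if u4.censored and u5.censored:
            out = Outcome.PERSIST
        elif (not u4.censored and not u5.censored
              and abs(u4.t_end - u5.t_end) <= tolerance_s):
            out = Outcome.SIMULTANEOUS_LOSS
        elif u5.censored or (not u4.censored and u4.t_end <= u5.t_end):
            out = Outcome.U4_FIRST
        else:
            out = Outcome.U5_FIRST
        pair.outcome = out
        counts[out.value] += 1
        total += 1
    return PathwayTally(counts, total)


def multi_binding_summary(pairs: Sequence[CoincidenceEvent],
                          n_molecules: int | None = None) -> dict:
    """Per-molecule tri-snRNP binding statistics.

    Returns the distribution of binding-event counts per molecule, the
    number of molecules with >= 2 activation (U4-first) rounds, and the
    number of molecules where two tri-snRNP events overlap in time.
    """
    by_mol: dict[int, list[CoincidenceEvent]] = {}
    for p in pairs:
        by_mol.setdefault(p.molecule_id, []).append(p)
    counts = {mol: len(v) for mol, v in by_mol.items()}
    repeat_act = sum(
        1 for v in by_mol.values()
        if sum(p.outcome == Outcome.U4_FIRST for p in v) >= 2)
    overlapping = 0
    for v in by_mol.values():
        evs = sorted(v, key=lambda p: p.t_arrival)
        for prev, nxt in zip(evs, evs[1:]):
            prev_end = max(prev.u4.t_end, prev.u5.t_end)
            if nxt.t_arrival < prev_end:
                overlapping += 1
                break
    n_total = n_molecules if n_molecules is not None else len(by_mol)
    dist: dict[int, int] = {}
    for c in counts.values():
        dist[c] = dist.get(c, 0) + 1
    if n_total > len(by_mol):
        dist[0] = dist.get(0, 0) + n_total - len(by_mol)
    return {
        "events_per_molecule": dist,
        "n_molecules": n_total,
        "n_multiple_binding": sum(1 for c in counts.values() if c >= 2),
        "n_repeat_activation": repeat_act,
        "repeat_activation_percent":
            round(100.0 * repeat_act / n_total, 1) if n_total else 0.0,
        "n_overlapping_trisnrnp": overlapping,
    }


@dataclass
class RebindingResult:
    n_eligible: int
    n_rebinding: int
    percent: float
    rate_per_min: float | None
    background_rate_per_min: float | None


def rebinding_analysis(pairs: Sequence[CoincidenceEvent],
                       u4_events: Sequence[EventInterval],
                       tolerance_s: float = 3.0,
                       background_rate_per_min: float | None = None
                       ) -> RebindingResult:
    """U4 reappearance while U5 persists after a U4-first outcome.

    Eligible cases are activation (U4-first) pairs; a rebinding instance
    is a U4 event starting after that pair's U4 departure (beyond the
    simultaneity tolerance) and before its U5 departure.  The rate is
    instances per minute of eligible U5-visible time, compared to the
    nonspecific background binding rate when one is supplied.
    """
    u4_by_mol: dict[int, list[EventInterval]] = {}
    for ev in u4_events:
        u4_by_mol.setdefault(ev.molecule_id, []).append(ev)
    eligible = [p for p in pairs if p.outcome == Outcome.U4_FIRST]
    n_rebind = 0
    visible_s = 0.0
    for p in eligible:
        window = (p.u4.t_end + tolerance_s, p.u5.t_end)
        visible_s += max(window[1] - window[0], 0.0)
        if any(window[0] < ev.t_start < window[1]
               for ev in u4_by_mol.get(p.molecule_id, [])):
            n_rebind += 1
    percent = 100.0 * n_rebind / len(eligible) if eligible else 0.0
    rate = n_rebind / (visible_s / 60.0) if visible_s > 0 else None
    if background_rate_per_min is None:
        import warnings
        warnings.warn("no background rate supplied; comparison omitted")
    return RebindingResult(len(eligible), n_rebind, percent, rate,
                           background_rate_per_min)


@dataclass
class OrderingRecord:
    """Per-molecule offsets between U4 release and NTC arrival.

    delta = t(U4 release) - t(NTC arrival): positive when the NTC arrived
    before U4 release, negative when it arrived after.
    """

    deltas: np.ndarray
    fraction_negative: float
    n_excluded: int
    bin_edges: np.ndarray
    histogram: np.ndarray


_DEFAULT_ORDER_BINS = np.concatenate(
    [[-3600.0], np.arange(-200.0, 200.0 + 1e-9, 20.0), [3600.0]])


def ordering_offsets(u4_events: Sequence[EventInterval],
                     ntc_events: Sequence[EventInterval],
                     bin_edges: np.ndarray | None = None) -> OrderingRecord:
    """Offsets delta = tU4release - tNTCarrival, one per molecule.

    For each molecule with at least one uncensored U4 departure and one
    NTC arrival, the pair with minimal |delta| is kept; molecules lacking
    either event are excluded and counted.
    """
    edges = _DEFAULT_ORDER_BINS if bin_edges is None else bin_edges
    u4_rel: dict[int, list[float]] = {}
    for ev in u4_events:
        if not ev.censored:
            u4_rel.setdefault(ev.molecule_id, []).append(ev.t_end)
    ntc_arr: dict[int, list[float]] = {}
    for ev in ntc_events:
        ntc_arr.setdefault(ev.molecule_id, []).append(ev.t_start)
    deltas = []
    n_excluded = 0
    for mol in sorted(set(u4_rel) | set(ntc_arr)):
        if mol not in u4_rel or mol not in ntc_arr:
            n_excluded += 1
            continue
        best = min((rel - arr for rel in u4_rel[mol]
                    for arr in ntc_arr[mol]), key=abs)
        deltas.append(best)
    deltas = np.asarray(deltas, dtype=float)
    frac_neg = float(np.mean(deltas < 0)) if deltas.size else float("nan")
    hist, _ = np.histogram(deltas, bins=edges)
    return OrderingRecord(deltas, frac_neg, n_excluded, np.asarray(edges),
                          hist.astype(float))


def randomized_control(u4_events: Sequence[EventInterval],
                       ntc_events: Sequence[EventInterval],
                       n_shuffles: int = 100, seed: int = 0,
                       bin_edges: np.ndarray | None = None) -> OrderingRecord:
    """Shuffled-control offset histogram.

    NTC arrival-time lists are permuted across molecules (U4 release
    times stay put), offsets are recomputed, and the histogram is
    averaged over ``n_shuffles`` seeded permutations.
    """
    mols = sorted({ev.molecule_id for ev in ntc_events})
    if len(mols) < 2:
        raise ValueError("need >= 2 molecules with NTC events to shuffle")
    edges = _DEFAULT_ORDER_BINS if bin_edges is None else np.asarray(bin_edges)
    ntc_by_mol: dict[int, list[EventInterval]] = {}
    for ev in ntc_events:
        ntc_by_mol.setdefault(ev.molecule_id, []).append(ev)
    rng = np.random.default_rng(seed)
    acc = np.zeros(len(edges) - 1)
    all_deltas = []
    n_excl = 0
    for _ in range(n_shuffles):
        perm = rng.permutation(mols)
        shuffled = []
        for new_mol, old_mol in zip(mols, perm):
            for ev in ntc_by_mol[old_mol]:
                shuffled.append(EventInterval(
                    new_mol, ev.channel, ev.t_start, ev.t_end, ev.censored))
        rec = ordering_offsets(u4_events, shuffled, edges)
        acc += rec.histogram
        all_deltas.append(rec.deltas)
        n_excl = rec.n_excluded
    deltas = np.concatenate(all_deltas) if all_deltas else np.empty(0)
    frac_neg = float(np.mean(deltas < 0)) if deltas.size else float("nan")
    return OrderingRecord(deltas, frac_neg, n_excl, np.asarray(edges),
                          acc / n_shuffles)


def dwell_correlation(x: Sequence[float], y: Sequence[float],
                      n_perm: int = 1000, seed: int = 0
                      ) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided permutation p-value.

    Used to ask whether the time to U4 release predicts the subsequent
    U5 dwell.  Raises on all-tied input where the rank correlation is
    undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 5:
        raise ValueError("need >= 5 paired dwells")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("rank correlation undefined for all-tied input")
    rho = float(stats.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        r = stats.spearmanr(x, rng.permutation(y)).statistic
        if abs(r) >= abs(rho) - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return rho, float(p)


@dataclass
class BackgroundRate:
    rate_per_aoi_min: float
    ci_low: float
    ci_high: float
    n_events: int

    def __iter__(self):
        yield from (self.rate_per_aoi_min, self.ci_low, self.ci_high)


def background_rate(n_events: int, n_aois: int,
                    duration_min: float,
                    ci_level: float = 0.95) -> BackgroundRate:
    """Nonspecific binding rate (events / AOI / min) with exact Poisson CI."""
    if duration_min <= 0 or n_aois <= 0:
        raise ValueError("need positive duration and AOI count")
    exposure = n_aois * duration_min
    alpha = 1 - ci_level
    lo = stats.chi2.ppf(alpha / 2, 2 * n_events) / 2 if n_events > 0 else 0.0
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * (n_events + 1)) / 2
    return BackgroundRate(n_events / exposure, lo / exposure, hi / exposure,
                          n_events)
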