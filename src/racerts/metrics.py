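"""Quantitative benchmark framework for conformer-ensemble generators.

Implements wall-time cost normalization, combined-reference-ensemble
construction, Butina sphere-exclusion clustering, space exploration
(precision / recall / F1), space distribution (Jensen-Shannon divergence of
RMSD-to-input distributions, base-2 logs so values lie in [0, 1]), success
rate, top-N accuracy, and activation-energy error statistics with Boltzmann
averaging.

Two conformers count as *identical* throughout when their heavy-atom RMSD is
below 0.125 A and their energies differ by less than 0.05 kcal/mol
(:func:`racerts.pruning.conformers_identical`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ValidationError
from .pruning import PruneConfig, conformers_identical, prune_energy, prune_rmsd, rmsd
from .structure_io import Ensemble, Member, Structure

log = logging.getLogger(__name__)

#: Gas constant in kcal/(mol K).
R_KCAL = 8.314462618 / 4184.0

DEFAULT_TEMPERATURE = 298.15
DEFAULT_CLUSTER_THRESHOLD = 1.0
DEFAULT_BIN_WIDTH = 0.25

__all__ = [
    "TimingRecord",
    "ClusterStats",
    "RmsdDistribution",
    "SuccessRate",
    "MetricReport",
    "comp_cost",
    "combine_ensembles",
    "butina_cluster",
    "space_exploration",
    "js_divergence",
    "space_distribution",
    "success_rate",
    "top_n_accuracy",
    "boltzmann_average",
    "delta_e_lowe",
    "delta_e_marc",
    "tukey_summary",
]


@dataclass(frozen=True)
class TimingRecord:
    method: str
    reaction: str
    wall_time: float

    def __post_init__(self):
        if self.wall_time <= 0:
            raise ValidationError("wall_time must be positive")


@dataclass
class ClusterStats:
    n_in_cluster: int
    n_total: int
    n_clusters: int
    n_total_clusters: int

    @property
    def precision(self) -> float:
        return self.n_in_cluster / self.n_total if self.n_total else 0.0

    @property
    def recall(self) -> float:
        return self.n_clusters / self.n_total_clusters if self.n_total_clusters else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2.0 * p * r / (p + r) if p + r > 0 else 0.0


@dataclass
class RmsdDistribution:
    """RMSD values of ensemble members to the generator's input structure."""

    samples: np.ndarray
    bin_width: float = DEFAULT_BIN_WIDTH

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.samples.size == 0:
            raise ValidationError("an RMSD distribution needs at least one sample")
        if np.any(self.samples < 0):
            raise ValidationError("RMSD samples must be non-negative")

    @classmethod
    def from_ensemble(cls, ensemble: Ensemble, reference: Structure,
                      bin_width: float = DEFAULT_BIN_WIDTH) -> "RmsdDistribution":
        vals = [rmsd(m.structure, reference) for m in ensemble]
        return cls(np.array(vals), bin_width=bin_width)


@dataclass(frozen=True)
class SuccessRate:
    value: float
    n_reactions_with_success: int


def comp_cost(method_times: Dict[str, float], reference_times: Dict[str, float]) -> float:
    """Mean over reactions of wall-time ratio method / reference."""
    missing = set(method_times) - set(reference_times)
    if missing:
        raise ValidationError(f"no reference timing for reactions: {sorted(missing)}")
    if not method_times:
        raise ValidationError("no timings given")
    ratios = [method_times[r] / reference_times[r] for r in sorted(method_times)]
    return float(np.mean(ratios))


def combine_ensembles(
    ensembles: Sequence[Ensemble],
    window: float = 6.0,
    rmsd_threshold: float = 0.125,
) -> Ensemble:
    """Best-approximation reference ensemble from all methods' outputs.

    Concatenate, energy-sort, prune to the energy window, then deduplicate by
    greedy RMSD sweep.
    """
    if not ensembles:
        raise ValidationError("need at least one ensemble to combine")
    members: List[Member] = []
    ref_symbols = ensembles[0][0].structure.symbols if len(ensembles[0]) else None
    for ens in ensembles:
        for m in ens:
            if m.structure.symbols != ref_symbols:
                raise ValidationError("cannot combine ensembles with mixed atom lists")
            members.append(m)
    combined = Ensemble(members, reference_input=ensembles[0].reference_input)
    combined = combined.sorted_by_energy()
    combined = prune_energy(combined, window)
    return prune_rmsd(combined, PruneConfig(rmsd_threshold=rmsd_threshold,
                                            energy_window=window))


def _pairwise_rmsd(members: Sequence[Structure]) -> np.ndarray:
    n = len(members)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = rmsd(members[i], members[j])
    return mat


def butina_cluster(
    members: Sequence[Structure],
    rmsd_threshold: float = DEFAULT_CLUSTER_THRESHOLD,
    precomputed: Optional[np.ndarray] = None,
) -> List[List[int]]:
    """Butina sphere-exclusion clustering on the pairwise heavy-atom RMSD matrix.

    Repeatedly picks the member with the most unassigned neighbors within the
    threshold as a centroid (ties: lowest index), assigns its neighborhood,
    and removes it.  Returns clusters in selection order, each with the
    centroid first; singletons allowed.
    """
    n = len(members)
    if n == 0:
        raise ValidationError("cannot cluster an empty member list")
    mat = precomputed if precomputed is not None else _pairwise_rmsd(members)
    neigh = [set(np.flatnonzero(mat[i] <= rmsd_threshold)) | {i} for i in range(n)]
    unassigned = set(range(n))
    clusters: List[List[int]] = []
    while unassigned:
        counts = {i: len(neigh[i] & unassigned) for i in unassigned}
        centroid = min(unassigned, key=lambda i: (-counts[i], i))
        cluster = sorted(neigh[centroid] & unassigned)
        cluster.remove(centroid)
        clusters.append([centroid] + cluster)
        unassigned -= set(clusters[-1])
    return clusters


def space_exploration(
    method_ensembles: Dict[str, Ensemble],
    combined: Ensemble,
    cluster_threshold: float = DEFAULT_CLUSTER_THRESHOLD,
) -> Dict[str, ClusterStats]:
    """Per-method precision/recall/F1 against the clustered combined ensemble.

    A method conformer "is in a cluster" iff it is identical (RMSD + energy
    criterion) to some combined-ensemble member; it then inherits that
    member's cluster.  Conformers pruned away during combination count as
    absent.
    """
    if len(combined) == 0:
        raise ValidationError("combined ensemble is empty")
    clusters = butina_cluster([m.structure for m in combined],
                              rmsd_threshold=cluster_threshold)
    member_cluster = {}
    for cid, idxs in enumerate(clusters):
        for k in idxs:
            member_cluster[k] = cid
    out = {}
    for method, ens in method_ensembles.items():
        matched_clusters = set()
        n_in_cluster = 0
        for m in ens:
            hit = None
            for k, cm in enumerate(combined):
                if conformers_identical(m, cm):
                    hit = k
                    break
            if hit is not None:
                n_in_cluster += 1
                matched_clusters.add(member_cluster[hit])
        out[method] = ClusterStats(
            n_in_cluster=n_in_cluster,
            n_total=len(ens),
            n_clusters=len(matched_clusters),
            n_total_clusters=len(clusters),
        )
    return out


def js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence between two histograms, base-2 logs.

    Inputs are normalized in place; zero-count bins follow the 0 log 0 = 0
    convention.  Result lies in [0, 1].
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValidationError("histograms must share one binning")
    if p.sum() <= 0 or q.sum() <= 0:
        raise ValidationError("histograms must have positive mass")
    p = p / p.sum()
    q = q / q.sum()
    m = 0.5 * (p + q)

    def kl(a, b):
        mask = a > 0
        return float(np.sum(a[mask] * np.log2(a[mask] / b[mask])))

    return 0.5 * kl(p, m) + 0.5 * kl(q, m)


def space_distribution(
    method_rmsds: RmsdDistribution, combined_rmsds: RmsdDistribution
) -> float:
    """JS divergence of the two RMSD-to-input distributions on shared bins."""
    width = method_rmsds.bin_width
    hi = max(method_rmsds.samples.max(), combined_rmsds.samples.max())
    n_bins = max(1, int(math.ceil(hi / width + 1e-12)))
    edges = np.linspace(0.0, n_bins * width, n_bins + 1)
    p, _ = np.histogram(method_rmsds.samples, bins=edges)
    q, _ = np.histogram(combined_rmsds.samples, bins=edges)
    return js_divergence(p, q)


def success_rate(outcomes: Sequence[Tuple[int, int]]) -> SuccessRate:
    """Mean per-reaction fraction of conformers surviving the validity pipeline."""
    if not outcomes:
        raise ValidationError("no outcomes given")
    fracs = []
    n_with = 0
    for n_success, n_total in outcomes:
        if n_total < 1:
            raise ValidationError("each reaction needs n_total >= 1")
        if n_success > n_total:
            raise ValidationError("n_successful cannot exceed n_total")
        fracs.append(n_success / n_total)
        n_with += 1 if n_success >= 1 else 0
    return SuccessRate(float(np.mean(fracs)), n_with)


def _first_match_rank(ranking: Sequence[Member], target: Member) -> float:
    """1-based rank of the first conformer identical to ``target`` (inf if none)."""
    for pos, m in enumerate(ranking, start=1):
        if conformers_identical(m, target):
            return float(pos)
    return math.inf


def top_n_accuracy(
    per_method_rankings: Dict[str, Sequence[Sequence[Member]]],
    overall_lowest: Sequence[Member],
    n: int,
) -> Dict[str, float]:
    """Fraction of reactions where the overall lowest conformer sits in a
    method's first ``n`` conformers (the method's own energy order).

    ``per_method_rankings[method][r]`` is the ranked conformer list for
    reaction ``r``; empty rankings count as misses.
    """
    n_rxn = len(overall_lowest)
    out = {}
    for method, rankings in per_method_rankings.items():
        if len(rankings) != n_rxn:
            raise ValidationError(
                f"method {method!r} has {len(rankings)} rankings for {n_rxn} reactions"
            )
        hits = 0
        for ranking, best in zip(rankings, overall_lowest):
            if not len(ranking):
                log.warning("method %r: empty ranking counted as miss", method)
                continue
            if _first_match_rank(list(ranking), best) <= n:
                hits += 1
        out[method] = hits / n_rxn
    return out


def boltzmann_average(
    energies: Sequence[float], temperature: float = DEFAULT_TEMPERATURE
) -> float:
    """Boltzmann-weighted mean energy, shifted by the minimum for stability."""
    e = np.asarray(list(energies), dtype=float)
    if e.size == 0:
        raise ValidationError("need at least one energy")
    if temperature <= 0:
        raise ValidationError("temperature must be positive")
    shifted = e - e.min()
    w = np.exp(-shifted / (R_KCAL * temperature))
    return float(np.sum(e * w) / np.sum(w))


def delta_e_lowe(
    method_lowest: Dict[str, Optional[float]], overall_lowest_energy: float
) -> Dict[str, float]:
    """Per-method lowest-valid-conformer energy gap to the overall lowest.

    Methods mapping to ``None`` (no valid conformer for this reaction) are
    excluded with a log message.
    """
    out = {}
    for method, e in method_lowest.items():
        if e is None:
            log.warning("method %r excluded: no valid conformer", method)
            continue
        out[method] = float(e - overall_lowest_energy)
    return out


def delta_e_marc(
    method_subset_energies: Dict[str, Sequence[float]],
    all_subset_energies: Sequence[float],
    temperature: float = DEFAULT_TEMPERATURE,
) -> Dict[str, float]:
    """Difference of Boltzmann-averaged energies: method subset vs full union."""
    if not len(list(all_subset_energies)):
        raise ValidationError("the union subset must not be empty")
    e_all = boltzmann_average(all_subset_energies, temperature)
    return {
        method: boltzmann_average(energies, temperature) - e_all
        for method, energies in method_subset_energies.items()
    }


def tukey_summary(values: Sequence[float]) -> Dict[str, float]:
    """Median and Tukey boxplot statistics of a value distribution."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValidationError("no values to summarize")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo = v[v >= q1 - 1.5 * iqr].min()
    hi = v[v <= q3 + 1.5 * iqr].max()
    return {
        "median": float(med), "q1": float(q1), "q3": float(q3),
        "whisker_low": float(lo), "whisker_high": float(hi),
        "n": int(v.size),
    }


@dataclass
class MetricReport:
    """Per-reaction metric values and their across-reaction averages."""

    per_reaction: Dict[str, Dict[str, Dict[str, float]]] = field(default_factory=dict)
    averages: Dict[str, Dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"per_reaction": self.per_reaction, "averages": self.averages}


def benchmark_report(
    ensembles: Dict[str, Dict[str, Ensemble]],
    inputs: Dict[str, Structure],
    timings: Optional[Sequence[TimingRecord]] = None,
    reference_method: Optional[str] = None,
    temperature: float = DEFAULT_TEMPERATURE,
    cluster_threshold: float = DEFAULT_CLUSTER_THRESHOLD,
) -> MetricReport:
    """Compute all ensemble-level metrics for a method x reaction grid.

    ``ensembles[method][reaction]`` are ranked ensembles; ``inputs`` maps
    reaction to the common input structure.  Validity labels and marc subsets
    are external inputs and not part of this orchestrator.
    """
    methods = sorted(ensembles)
    reactions = sorted(inputs)
    report = MetricReport()
    per: Dict[str, Dict[str, Dict[str, float]]] = {m: {} for m in methods}

    combined_by_rxn = {}
    for rxn in reactions:
        pool = [ensembles[m][rxn] for m in methods if rxn in ensembles[m]]
        combined_by_rxn[rxn] = combine_ensembles(pool)

    for rxn in reactions:
        combined = combined_by_rxn[rxn]
        stats = space_exploration(
            {m: ensembles[m][rxn] for m in methods if rxn in ensembles[m]},
            combined, cluster_threshold=cluster_threshold,
        )
        comb_dist = RmsdDistribution.from_ensemble(combined, inputs[rxn])
        overall_lowest = min(
            (ensembles[m][rxn][0] for m in methods if rxn in ensembles[m] and len(ensembles[m][rxn])),
            key=lambda mm: mm.energy,
        )
        for m in methods:
            if rxn not in ensembles[m]:
                continue
            ens = ensembles[m][rxn]
            st = stats[m]
            dist = RmsdDistribution.from_ensemble(ens, inputs[rxn])
            row = {
                "precision": st.precision,
                "recall": st.recall,
                "f1": st.f1,
                "space_distribution": space_distribution(dist, comb_dist),
                "top1": 1.0 if _first_match_rank(list(ens)[:1], overall_lowest) <= 1 else 0.0,
                "top5": 1.0 if _first_match_rank(list(ens)[:5], overall_lowest) <= 5 else 0.0,
                "delta_e_lowe": float(ens[0].energy - overall_lowest.energy),
                "delta_e_marc": delta_e_marc(
                    {m: [mm.energy for mm in ens][:10]},
                    [mm.energy for mm in combined],
                    temperature,
                )[m],
            }
            per[m][rxn] = row

    timing_by_method: Dict[str, Dict[str, float]] = {}
    if timings:
        for rec in timings:
            timing_by_method.setdefault(rec.method, {})[rec.reaction] = rec.wall_time
        if reference_method is None or reference_method not in timing_by_method:
            raise ValidationError("timings given but no valid reference_method")

    for m in methods:
        rows = per[m].values()
        avg = {
            key: float(np.mean([r[key] for r in rows])) for key in next(iter(rows)).keys()
        } if rows else {}
        avg["space_exploration"] = avg.pop("f1", 0.0)
        if m in timing_by_method:
            avg["comp_cost"] = comp_cost(
                timing_by_method[m], timing_by_method[reference_method]
            )
        report.averages[m] = avg
    report.per_reaction = per
    return report
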