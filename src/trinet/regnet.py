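"""Direction-consistent TF-miRNA-mRNA network assembly and feedback-loop
detection.

Starting from consensus DEG calls, DEM calls and the two prediction tables,
the assembly proceeds in four steps:

1. overlap: keep TFs of called DEMs that are themselves called DEGs, and
   predicted targets of called DEMs (at a prediction-score floor) that are
   called DEGs;
2. sign filtering: an Activation edge TF->miRNA requires concordant
   regulation directions and a Repression edge discordant ones; a
   miRNA->target edge always requires discordant directions (miRNAs
   repress their targets); edges of unknown action are dropped;
3. triad assembly: only complete TF->miRNA->target paths survive, and every
   node must sit on at least one such path;
4. feedback loops: independently of step 3, a loop is recorded for every
   retained activating TF->miRNA edge whose miRNA lists that same TF among
   its predicted targets.

All symbols are canonical keys (see :mod:`trinet.dataio`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

from .dataio import DataError, RegPredictionTables


class DirectionalCall(NamedTuple):
    symbol: str
    layer: str      # 'TF' | 'miRNA' | 'target'
    direction: str  # 'up' | 'down'


class TFMirnaEdge(NamedTuple):
    tf: str
    mirna: str
    action: str


class MirnaTargetEdge(NamedTuple):
    mirna: str
    target: str
    score: float


@dataclass(frozen=True)
class FeedbackLoop:
    tf: str
    mirna: str
    tf_mirna_action: str
    target_score: float
    evidence: str = ""


@dataclass
class TriadNetwork:
    nodes: list[DirectionalCall] = field(default_factory=list)
    tf_mirna_edges: list[TFMirnaEdge] = field(default_factory=list)
    mirna_target_edges: list[MirnaTargetEdge] = field(default_factory=list)
    triads: list[tuple[str, str, str]] = field(default_factory=list)

    def layer_symbols(self, layer: str) -> list[str]:
        return [n.symbol for n in self.nodes if n.layer == layer]

    def validate(self) -> None:
        """Re-assert the structural invariants (every node on a triad,
        unique (symbol, layer) calls)."""
        on_triad = {s for t in self.triads for s in t}
        off = [n.symbol for n in self.nodes if n.symbol not in on_triad]
        if off:
            raise DataError(f"nodes off every triad: {off}")
        keys = [(n.symbol, n.layer) for n in self.nodes]
        if len(set(keys)) != len(keys):
            raise DataError("duplicate (symbol, layer) node calls")


def _check_direction(calls: dict[str, str], what: str) -> None:
    bad = {s: d for s, d in calls.items() if d not in ("up", "down")}
    if bad:
        raise DataError(f"{what}: directions must be 'up'/'down', got {bad}")


def overlap_tfs(
    deg_calls: dict[str, str],
    tables: RegPredictionTables,
    dem_calls: dict[str, str],
) -> dict[str, str]:
    """TFs regulating a called DEM that are themselves called DEGs.

    Returns canonical TF symbol -> DEG direction.
    """
    _check_direction(deg_calls, "deg_calls")
    _check_direction(dem_calls, "dem_calls")
    tm = tables.tf_mirna
    relevant = tm[tm["mirna_key"].isin(dem_calls)]
    return {tf: deg_calls[tf] for tf in sorted(set(relevant["tf_key"])) if tf in deg_calls}


def overlap_targets(
    deg_calls: dict[str, str],
    tables: RegPredictionTables,
    dem_calls: dict[str, str],
    score_cutoff: float = 50.0,
) -> dict[str, str]:
    """Predicted targets of called DEMs (score >= cutoff) that are called DEGs."""
    _check_direction(deg_calls, "deg_calls")
    _check_direction(dem_calls, "dem_calls")
    mt = tables.mirna_target
    relevant = mt[mt["mirna_key"].isin(dem_calls) & (mt["score"] >= score_cutoff)]
    return {g: deg_calls[g] for g in sorted(set(relevant["target_key"])) if g in deg_calls}


def filter_consistent_edges(
    tf_set: dict[str, str],
    dem_calls: dict[str, str],
    target_set: dict[str, str],
    tables: RegPredictionTables,
    score_cutoff: float = 50.0,
) -> tuple[list[TFMirnaEdge], list[MirnaTargetEdge]]:
    """Keep only sign-consistent regulation edges among DE symbols.

    Activation TF->miRNA: directions must match.  Repression TF->miRNA:
    directions must differ.  Unknown action: dropped.  miRNA->target:
    directions must differ (repression semantics), score >= cutoff.
    """
    tf_edges: list[TFMirnaEdge] = []
    for row in tables.tf_mirna.itertuples():
        tf, m, action = row.tf_key, row.mirna_key, row.action
        if tf not in tf_set or m not in dem_calls or action == "Unknown":
            continue
        same = tf_set[tf] == dem_calls[m]
        if (action == "Activation" and same) or (action == "Repression" and not same):
            tf_edges.append(TFMirnaEdge(tf, m, action))

    mt_edges: list[MirnaTargetEdge] = []
    for row in tables.mirna_target.itertuples():
        m, g, score = row.mirna_key, row.target_key, float(row.score)
        if m not in dem_calls or g not in target_set or score < score_cutoff:
            continue
        if dem_calls[m] != target_set[g]:
            mt_edges.append(MirnaTargetEdge(m, g, score))

    return sorted(tf_edges), sorted(mt_edges)


def assemble(
    tf_edges: list[TFMirnaEdge],
    mt_edges: list[MirnaTargetEdge],
    tf_set: dict[str, str],
    dem_calls: dict[str, str],
    target_set: dict[str, str],
) -> TriadNetwork:
    """Enumerate complete TF->miRNA->target triads and prune off-path nodes."""
    by_mirna: dict[str, list[MirnaTargetEdge]] = {}
    for e in mt_edges:
        by_mirna.setdefault(e.mirna, []).append(e)

    triads = sorted(
        (te.tf, te.mirna, me.target)
        for te in tf_edges
        for me in by_mirna.get(te.mirna, [])
    )
    tfs = {t for t, _, _ in triads}
    mirnas = {m for _, m, _ in triads}
    targets = {g for _, _, g in triads}

    nodes = (
        [DirectionalCall(s, "TF", tf_set[s]) for s in sorted(tfs)]
        + [DirectionalCall(s, "miRNA", dem_calls[s]) for s in sorted(mirnas)]
        + [DirectionalCall(s, "target", target_set[s]) for s in sorted(targets)]
    )
    net = TriadNetwork(
        nodes=nodes,
        tf_mirna_edges=sorted(e for e in tf_edges if e.mirna in mirnas and e.tf in tfs),
        mirna_target_edges=sorted(e for e in mt_edges if e.mirna in mirnas and e.target in targets),
        triads=triads,
    )
    net.validate()
    return net


def detect_loops(
    tf_edges: list[TFMirnaEdge],
    tables: RegPredictionTables,
    tf_set: dict[str, str],
) -> list[FeedbackLoop]:
    """TF-miRNA feedback loops: TF activates the miRNA, and the miRNA lists
    the TF among its predicted targets.

    The search runs over the sign-consistent TF->miRNA edges and the *full*
    target table (no score floor, no direction filter), so loops can involve
    miRNAs that were pruned from the triad network.
    """
    targets_of: dict[str, dict[str, float]] = {}
    for row in tables.mirna_target.itertuples():
        targets_of.setdefault(row.mirna_key, {})[row.target_key] = float(row.score)

    loops = []
    for e in tf_edges:
        if e.action != "Activation" or e.tf not in tf_set:
            continue
        score = targets_of.get(e.mirna, {}).get(e.tf)
        if score is not None:
            loops.append(
                FeedbackLoop(tf=e.tf, mirna=e.mirna, tf_mirna_action=e.action, target_score=score)
            )
    return sorted(loops, key=lambda l: (l.tf, l.mirna))


def build_network(
    deg_calls: dict[str, str],
    dem_calls: dict[str, str],
    tables: RegPredictionTables,
    score_cutoff: float = 50.0,
) -> tuple[TriadNetwork, list[FeedbackLoop]]:
    """Full assembly convenience wrapper: overlaps, sign filter, triads, loops."""
    tf_set = overlap_tfs(deg_calls, tables, dem_calls)
    target_set = overlap_targets(deg_calls, tables, dem_calls, score_cutoff=score_cutoff)
    tf_edges, mt_edges = filter_consistent_edges(
        tf_set, dem_calls, target_set, tables, score_cutoff=score_cutoff
    )
    net = assemble(tf_edges, mt_edges, tf_set, dem_calls, target_set)
    loops = detect_loops(tf_edges, tables, tf_set)
    return net, loops
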