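"""Readers and writers for expression matrices, regulation tables, PPI edge
lists and assembled networks.

All cross-source joins in the pipeline go through :func:`canonical_symbol`,
because the upstream databases disagree on capitalisation ("miR-155" vs
"mir-155") and on species prefixes ("mmu-miR-21" vs "miR-21").  Parsers keep
the first-seen display spelling for output but match case-insensitively.

Expression matrices are taken as already log2-transformed and normalised;
no normalisation is performed here.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"
ACTIONS = ("Activation", "Repression", "Unknown")


class DataError(ValueError):
    """Base class for malformed or inconsistent input data."""


class SchemaError(DataError):
    """A required column, row or value is missing or of the wrong type."""


class DesignError(DataError):
    """Sample/design bookkeeping is inconsistent with the matrix."""


_SPECIES_PREFIX = re.compile(r"^(hsa|mmu|rno)-", flags=re.IGNORECASE)


def canonical_symbol(symbol: str, kind: str = "gene") -> str:
    """Canonical join key for a gene/TF or miRNA symbol.

    Gene symbols are matched case-insensitively.  miRNA names additionally
    drop the species prefix, so ``mmu-miR-155``, ``miR-155`` and ``mir-155``
    all map to ``mir-155``.
    """
    s = str(symbol).strip()
    if not s:
        raise SchemaError("empty symbol")
    if kind == "mirna":
        s = _SPECIES_PREFIX.sub("", s)
    return s.lower()


@dataclass
class ExpressionStudy:
    """One study's log2 expression matrix plus its case/control design.

    ``values`` is features x samples.  ``design`` maps every sample ID to
    ``"case"`` or ``"control"``.
    """

    study_id: str
    features: list[str]
    samples: list[str]
    values: np.ndarray
    design: dict[str, str]
    feature_kind: str = "mRNA"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.features), len(self.samples)):
            raise DesignError(
                f"{self.study_id}: matrix shape {self.values.shape} does not "
                f"match {len(self.features)} features x {len(self.samples)} samples"
            )
        missing = [s for s in self.samples if s not in self.design]
        if missing:
            raise DesignError(f"{self.study_id}: samples missing from design: {missing}")
        bad = {g for g in self.design.values()} - {CASE, CONTROL}
        if bad:
            raise DesignError(f"{self.study_id}: unknown design labels {sorted(bad)}")
        for group in (CASE, CONTROL):
            if len(self.group_samples(group)) < 2:
                raise DesignError(f"{self.study_id}: fewer than 2 '{group}' samples")
        kind = "mirna" if self.feature_kind == "miRNA" else "gene"
        keys = [canonical_symbol(f, kind) for f in self.features]
        if len(set(keys)) != len(keys):
            raise SchemaError(f"{self.study_id}: duplicate feature symbols after canonicalization")
        self._key_index = {k: i for i, k in enumerate(keys)}

    # -- convenience accessors -------------------------------------------------

    def group_samples(self, group: str) -> list[str]:
        return [s for s in self.samples if self.design[s] == group]

    def group_values(self, group: str) -> np.ndarray:
        idx = [self.samples.index(s) for s in self.group_samples(group)]
        return self.values[:, idx]

    @property
    def symbol_kind(self) -> str:
        return "mirna" if self.feature_kind == "miRNA" else "gene"

    def feature_keys(self) -> list[str]:
        kind = self.symbol_kind
        return [canonical_symbol(f, kind) for f in self.features]

    def row(self, symbol: str) -> np.ndarray | None:
        """Values for one feature, matched canonically; None if absent."""
        i = self._key_index.get(canonical_symbol(symbol, self.symbol_kind))
        return None if i is None else self.values[i]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.features, columns=self.samples)


@dataclass
class RegPredictionTables:
    """TF->miRNA regulation table and miRNA->target prediction table.

    ``tf_mirna`` columns: tf, mirna, action, evidence (+ canonical tf_key,
    mirna_key).  ``mirna_target`` columns: mirna, target, score (+ mirna_key,
    target_key).  Duplicate canonical pairs are dropped with a warning; the
    first occurrence wins.
    """

    tf_mirna: pd.DataFrame
    mirna_target: pd.DataFrame

    @classmethod
    def from_frames(cls, tf_mirna: pd.DataFrame, mirna_target: pd.DataFrame) -> "RegPredictionTables":
        tm = tf_mirna.copy()
        mt = mirna_target.copy()

        for col in ("tf", "mirna"):
            if col not in tm.columns:
                raise SchemaError(f"tf_mirna table lacks required column '{col}'")
        if "action" not in tm.columns:
            raise SchemaError("tf_mirna table lacks required column 'action'")
        if "evidence" not in tm.columns:
            tm["evidence"] = ""
        tm["action"] = tm["action"].astype(str).str.strip().str.capitalize()
        bad_action = sorted(set(tm["action"]) - set(ACTIONS))
        if bad_action:
            raise SchemaError(f"unknown action types {bad_action}; expected one of {ACTIONS}")
        tm["tf_key"] = [canonical_symbol(s, "gene") for s in tm["tf"]]
        tm["mirna_key"] = [canonical_symbol(s, "mirna") for s in tm["mirna"]]
        n0 = len(tm)
        tm = tm.drop_duplicates(subset=["tf_key", "mirna_key"], keep="first").reset_index(drop=True)
        if len(tm) < n0:
            log.warning("dropped %d duplicate (tf, mirna) rows", n0 - len(tm))

        for col in ("mirna", "target", "score"):
            if col not in mt.columns:
                raise SchemaError(f"mirna_target table lacks required column '{col}'")
        score = pd.to_numeric(mt["score"], errors="coerce")
        if score.isna().any():
            raise SchemaError("non-numeric target score")
        if ((score < 0) | (score > 100)).any():
            raise SchemaError("target score outside [0, 100]")
        mt["score"] = score.astype(float)
        mt["mirna_key"] = [canonical_symbol(s, "mirna") for s in mt["mirna"]]
        mt["target_key"] = [canonical_symbol(s, "gene") for s in mt["target"]]
        n0 = len(mt)
        mt = mt.drop_duplicates(subset=["mirna_key", "target_key"], keep="first").reset_index(drop=True)
        if len(mt) < n0:
            log.warning("dropped %d duplicate (mirna, target) rows", n0 - len(mt))

        return cls(tf_mirna=tm, mirna_target=mt)

    def display_name(self, key: str) -> str:
        """First-seen display spelling for a canonical symbol key."""
        for frame, cols in ((self.tf_mirna, [("tf_key", "tf"), ("mirna_key", "mirna")]),
                            (self.mirna_target, [("mirna_key", "mirna"), ("target_key", "target")])):
            for kcol, dcol in cols:
                hit = frame.loc[frame[kcol] == key, dcol]
                if len(hit):
                    return str(hit.iloc[0])
        return key


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def read_design(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample", "group"}.issubset(df.columns):
        raise SchemaError(f"{path}: design file needs columns 'sample' and 'group'")
    return dict(zip(df["sample"], df["group"]))


def read_expression_matrix(
    path: str | Path,
    design_path: str | Path,
    feature_kind: str = "mRNA",
    study_id: str | None = None,
) -> ExpressionStudy:
    """Read a TSV expression matrix (header = sample IDs, column 1 = symbols).

    Rows whose symbols collapse to the same canonical key are reduced to the
    row with the highest mean expression (logged as a warning).
    """
    if feature_kind not in ("mRNA", "miRNA"):
        raise SchemaError(f"feature_kind must be 'mRNA' or 'miRNA', got {feature_kind!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise SchemaError(f"{path}: non-numeric expression values ({exc})") from None
    if df.empty:
        raise SchemaError(f"{path}: empty expression matrix")

    kind = "mirna" if feature_kind == "miRNA" else "gene"
    keys = pd.Index([canonical_symbol(s, kind) for s in df.index])
    if keys.has_duplicates:
        means = df.mean(axis=1).to_numpy()
        order = np.lexsort((-means, keys.to_numpy()))  # per key, highest mean first
        first = pd.Series(order).groupby(keys.to_numpy()[order], sort=False).first()
        keep = np.sort(first.to_numpy())
        n_dropped = len(df) - len(keep)
        log.warning("%s: collapsed %d duplicate feature rows (highest mean kept)", path, n_dropped)
        df = df.iloc[keep]

    design = read_design(design_path)
    missing = [s for s in df.columns if s not in design]
    if missing:
        raise DesignError(f"{path}: samples absent from design: {missing}")
    return ExpressionStudy(
        study_id=study_id or Path(path).stem,
        features=[str(s) for s in df.index],
        samples=[str(c) for c in df.columns],
        values=df.to_numpy(),
        design={s: design[s] for s in df.columns},
        feature_kind=feature_kind,
    )


def write_expression_study(study: ExpressionStudy, matrix_path: str | Path, design_path: str | Path) -> None:
    study.frame().to_csv(matrix_path, sep="\t", index_label="feature")
    pd.DataFrame(
        {"sample": study.samples, "group": [study.design[s] for s in study.samples]}
    ).to_csv(design_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Prediction tables and PPI edge lists
# ---------------------------------------------------------------------------

def read_prediction_tables(tf_path: str | Path, target_path: str | Path) -> RegPredictionTables:
    tm = pd.read_csv(tf_path, sep="\t", dtype=str)
    mt = pd.read_csv(target_path, sep="\t")
    return RegPredictionTables.from_frames(tm, mt)


def write_prediction_tables(tables: RegPredictionTables, tf_path: str | Path, target_path: str | Path) -> None:
    tables.tf_mirna[["tf", "mirna", "action", "evidence"]].to_csv(tf_path, sep="\t", index=False)
    tables.mirna_target[["mirna", "target", "score"]].to_csv(target_path, sep="\t", index=False)


def read_ppi_edges(path: str | Path) -> nx.Graph:
    """Read a 2-column TSV edge list into an undirected simple graph."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: PPI edge list needs 2 columns")
    g = nx.Graph()
    a, b = df.columns[:2]
    n_self = 0
    for u, v in zip(df[a], df[b]):
        cu, cv = canonical_symbol(u), canonical_symbol(v)
        if cu == cv:
            n_self += 1
            continue
        g.add_edge(cu, cv)
    if n_self:
        log.warning("%s: dropped %d self-loop edges", path, n_self)
    return g


def write_ppi_edges(graph: nx.Graph, path: str | Path) -> None:
    rows = sorted(tuple(sorted(e)) for e in graph.edges())
    pd.DataFrame(rows, columns=["protein_a", "protein_b"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Assembled networks (GraphML / SIF)
# ---------------------------------------------------------------------------

def network_to_digraph(net) -> nx.DiGraph:
    """TriadNetwork -> nx.DiGraph with node attrs (layer, direction) and edge
    attrs (interaction, action, score)."""
    g = nx.DiGraph()
    layers: dict[str, set[str]] = {}
    directions: dict[str, str] = {}
    for call in net.nodes:
        layers.setdefault(call.symbol, set()).add(call.layer)
        directions[call.symbol] = call.direction
    for sym in sorted(layers):
        g.add_node(sym, layer=";".join(sorted(layers[sym])), direction=directions[sym])
    for tf, mirna, action in net.tf_mirna_edges:
        token = "activates" if action == "Activation" else "represses"
        g.add_edge(tf, mirna, interaction=token, action=action)
    for mirna, target, score in net.mirna_target_edges:
        g.add_edge(mirna, target, interaction="represses", action="Repression", score=float(score))
    return g


def write_network(net, path: str | Path, format: str = "GraphML") -> None:
    """Write an assembled tripartite network.

    GraphML keeps all node and edge attributes.  SIF writes one
    ``source<TAB>relation<TAB>target`` line per edge with relation tokens
    ``activates``/``represses``, plus a ``<path>.nodes.tsv`` sidecar carrying
    node layer and direction (SIF itself has no attribute syntax).
    """
    fmt = format.lower()
    g = network_to_digraph(net)
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v, data in sorted(g.edges(data=True)):
                fh.write(f"{u}\t{data['interaction']}\t{v}\n")
        sidecar = Path(str(path) + ".nodes.tsv")
        pd.DataFrame(
            [(n, d["layer"], d["direction"]) for n, d in sorted(g.nodes(data=True))],
            columns=["symbol", "layer", "direction"],
        ).to_csv(sidecar, sep="\t", index=False)
    else:
        raise SchemaError(f"unknown network format {format!r}; use 'GraphML' or 'SIF'")


def read_network_graphml(path: str | Path) -> nx.DiGraph:
    return nx.read_graphml(path)


def read_network_sif(path: str | Path) -> nx.DiGraph:
    g = nx.DiGraph()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            u, rel, v = line.split("\t")
            g.add_edge(u, v, interaction=rel)
    sidecar = Path(str(path) + ".nodes.tsv")
    if sidecar.exists():
        nodes = pd.read_csv(sidecar, sep="\t", dtype=str)
        for _, r in nodes.iterrows():
            g.add_node(r["symbol"], layer=r["layer"], direction=r["direction"])
    return g


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

DEFAULT_THRESHOLDS = {
    "lfc": 1.0,            # |log2FC| >= lfc passes
    "fdr": 0.05,           # BH q < fdr passes
    "rra_alpha": 0.05,     # Bonferroni-corrected rho call threshold
    "rra_mode": "full",    # 'full' ranked lists or 'thresholded'
    "score_cutoff": 50.0,  # miRNA-target prediction score floor
    "degree_cutoff": 3,    # MCODE seeding
    "kcore_filter": 4,     # MCODE final module filter
    "vwp": 0.2,            # MCODE vertex weight percentage
    "haircut": True,
    "r_cut": 0.3,          # |r| > r_cut flags a correlation
    "p_cut": 0.05,
    "auc_cut": 0.9,        # AUC > auc_cut flags a good marker
}


def load_config(path: str | Path | None) -> dict:
    """Load a YAML run config; missing keys fall back to the defaults above."""
    cfg = dict(DEFAULT_THRESHOLDS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise SchemaError(f"{path}: config must be a YAML mapping")
        cfg.update(user)
    return cfg
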