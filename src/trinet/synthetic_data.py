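"""Synthetic multi-study expression data with planted, recorded ground truth.

The generator emulates the inputs of the real screen: several independent
case/control mRNA studies sharing a gene universe with a common set of true
differentially expressed genes, one miRNA study, TF->miRNA and miRNA->target
prediction tables containing planted direction-consistent edges plus decoy
(sign-inconsistent) edges and random filler, and a PPI graph of an
Erdos-Renyi background with planted cliques.

Expression values are log2-scale: per-study baseline ~ Uniform(4, 12) per
feature, plus the signed planted effect in case samples, plus Gaussian noise.
Planted effects have |delta| >= 1 so they are threshold-relevant; non-DE
features have effect exactly 0.

Every planted triad satisfies the sign-consistency rule (TF and miRNA share
a direction, the target opposes the miRNA); every decoy violates it in one
of three ways: an activating TF over a discordant miRNA, a repression edge
with concordant signs, or a miRNA "target" moving with its miRNA.  All
randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .dataio import (
    DataError,
    ExpressionStudy,
    RegPredictionTables,
    canonical_symbol,
    write_expression_study,
    write_ppi_edges,
    write_prediction_tables,
)


class ConfigError(DataError):
    """The generator configuration is infeasible."""


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic screen.

    Defaults: three mRNA studies and one miRNA study of 10 samples per
    group, planted |log2FC| effects of 2 with noise sd 0.5 on the log2
    scale, and a G(n, 0.05) PPI background with planted cliques of sizes
    8, 6 and 5.
    """

    n_studies: int = 3
    samples_per_group: int = 10
    n_genes: int = 2000
    n_mirnas: int = 150
    n_tfs: int = 30
    effect_size: float = 2.0
    noise_sd: float = 0.5
    n_de_genes: int = 40
    n_de_mirnas: int = 20
    n_triads: int = 5
    n_loops: int = 3
    n_decoys_per_class: int = 2
    n_filler_tf_edges: int = 60
    n_filler_target_edges: int = 200
    ppi_n_background: int = 60
    ppi_edge_prob: float = 0.05
    planted_module_sizes: tuple = (8, 6, 5)
    baseline_range: tuple = (4.0, 12.0)


@dataclass
class TruthRecord:
    """Planted ground truth, keyed by canonical symbols."""

    true_degs: dict[str, float]
    true_dems: dict[str, float]
    planted_triads: list[tuple[str, str, str]]
    planted_loops: list[tuple[str, str]]
    decoy_edges: list[dict]
    planted_modules: list[frozenset]
    seed: int

    def validate(self) -> None:
        for tf, m, g in self.planted_triads:
            if np.sign(self.true_degs[tf]) != np.sign(self.true_dems[m]):
                raise DataError(f"triad ({tf},{m},{g}): TF and miRNA signs differ")
            if np.sign(self.true_degs[g]) == np.sign(self.true_dems[m]):
                raise DataError(f"triad ({tf},{m},{g}): target must oppose the miRNA")
        for tf, m in self.planted_loops:
            if np.sign(self.true_degs[tf]) != np.sign(self.true_dems[m]):
                raise DataError(f"loop ({tf},{m}): TF and miRNA signs differ")
        for mod in self.planted_modules:
            if len(mod) < 4:
                raise DataError("planted module smaller than 4 nodes")


@dataclass
class SyntheticDataset:
    studies: list[ExpressionStudy]
    mirna_study: ExpressionStudy
    tables: RegPredictionTables
    ppi: nx.Graph
    truth: TruthRecord
    config: GeneratorConfig


def _take(pool: list, n: int, what: str) -> list:
    if len(pool) < n:
        raise ConfigError(f"not enough {what}: need {n} more, have {len(pool)}")
    out = pool[:n]
    del pool[:n]
    return out


def generate_dataset(config: GeneratorConfig | None = None, seed: int = 0) -> SyntheticDataset:
    """Generate studies, prediction tables, a PPI graph and the truth record."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)

    if cfg.n_triads > cfg.n_tfs * cfg.n_mirnas:
        raise ConfigError("more triads requested than TF x miRNA pairs")
    if cfg.n_tfs >= cfg.n_genes:
        raise ConfigError("n_genes must exceed n_tfs (TFs are part of the gene universe)")
    if abs(cfg.effect_size) < 1 and cfg.effect_size != 0:
        raise ConfigError("planted |effect_size| must be >= 1 (or 0 for a null dataset)")

    tf_symbols = [f"Tf{i:02d}" for i in range(1, cfg.n_tfs + 1)]
    gene_symbols = tf_symbols + [f"Gene{i:04d}" for i in range(1, cfg.n_genes - cfg.n_tfs + 1)]
    mirna_symbols = [f"mir-{i}" for i in range(1, cfg.n_mirnas + 1)]

    tf_pool = list(rng.permutation(tf_symbols))
    gene_pool = list(rng.permutation([g for g in gene_symbols if g not in tf_symbols]))
    mirna_pool = list(rng.permutation(mirna_symbols))

    delta = float(cfg.effect_size)
    n_dec = cfg.n_decoys_per_class
    gene_fx: dict[str, float] = {}
    mirna_fx: dict[str, float] = {}

    def sign() -> float:
        return float(rng.choice([-1.0, 1.0]))

    # --- planted triads: TF and miRNA concordant, target discordant ----------
    triad_tfs = _take(tf_pool, cfg.n_triads, "TF symbols")
    triad_mirnas = _take(mirna_pool, cfg.n_triads, "miRNA symbols")
    triad_targets = _take(gene_pool, cfg.n_triads, "gene symbols")
    triads = []
    for tf, m, g in zip(triad_tfs, triad_mirnas, triad_targets):
        s = sign()
        gene_fx[tf], mirna_fx[m], gene_fx[g] = s * delta, s * delta, -s * delta
        triads.append((canonical_symbol(tf), canonical_symbol(m, "mirna"), canonical_symbol(g)))

    # --- planted feedback loops: TF activates miRNA, miRNA targets the TF ----
    loop_tfs = _take(tf_pool, cfg.n_loops, "TF symbols")
    loop_mirnas = _take(mirna_pool, cfg.n_loops, "miRNA symbols")
    loops = []
    for tf, m in zip(loop_tfs, loop_mirnas):
        s = sign()
        gene_fx[tf], mirna_fx[m] = s * delta, s * delta
        loops.append((canonical_symbol(tf), canonical_symbol(m, "mirna")))

    # --- decoys: one sign-inconsistency class each ----------------------------
    decoys: list[dict] = []
    decoy_tm_rows: list[tuple] = []
    decoy_mt_rows: list[tuple] = []
    for tf, m in zip(_take(tf_pool, n_dec, "TF symbols"), _take(mirna_pool, n_dec, "miRNA symbols")):
        s = sign()
        gene_fx[tf], mirna_fx[m] = s * delta, -s * delta
        decoys.append({"kind": "activation_discordant", "tf": canonical_symbol(tf),
                       "mirna": canonical_symbol(m, "mirna"), "action": "Activation"})
        decoy_tm_rows.append((tf, m, "Activation", "decoy:activation_discordant"))
    for tf, m in zip(_take(tf_pool, n_dec, "TF symbols"), _take(mirna_pool, n_dec, "miRNA symbols")):
        s = sign()
        gene_fx[tf], mirna_fx[m] = s * delta, s * delta
        decoys.append({"kind": "repression_concordant", "tf": canonical_symbol(tf),
                       "mirna": canonical_symbol(m, "mirna"), "action": "Repression"})
        decoy_tm_rows.append((tf, m, "Repression", "decoy:repression_concordant"))
    for m, g in zip(_take(mirna_pool, n_dec, "miRNA symbols"), _take(gene_pool, n_dec, "gene symbols")):
        s = sign()
        mirna_fx[m], gene_fx[g] = s * delta, s * delta
        decoys.append({"kind": "target_concordant", "mirna": canonical_symbol(m, "mirna"),
                       "target": canonical_symbol(g)})
        decoy_mt_rows.append((m, g, float(rng.uniform(55, 99))))

    # --- filler DE features up to the configured totals -----------------------
    if len(gene_fx) > cfg.n_de_genes:
        raise ConfigError(f"n_de_genes={cfg.n_de_genes} too small for planted structure ({len(gene_fx)})")
    if len(mirna_fx) > cfg.n_de_mirnas:
        raise ConfigError(f"n_de_mirnas={cfg.n_de_mirnas} too small for planted structure ({len(mirna_fx)})")
    for g in _take(gene_pool, cfg.n_de_genes - len(gene_fx), "gene symbols"):
        gene_fx[g] = sign() * delta
    for m in _take(mirna_pool, cfg.n_de_mirnas - len(mirna_fx), "miRNA symbols"):
        mirna_fx[m] = sign() * delta

    de_gene_keys = {canonical_symbol(g): e for g, e in gene_fx.items()}
    de_mirna_keys = {canonical_symbol(m, "mirna"): e for m, e in mirna_fx.items()}
    non_de_mirnas = [m for m in mirna_symbols if canonical_symbol(m, "mirna") not in de_mirna_keys]
    non_tf_genes = [g for g in gene_symbols if g not in tf_symbols]

    # --- prediction tables -----------------------------------------------------
    tm_rows = []
    for tf, m in zip(triad_tfs, triad_mirnas):
        tm_rows.append((tf, m, "Activation", "planted-triad"))
    for tf, m in zip(loop_tfs, loop_mirnas):
        tm_rows.append((tf, m, "Activation", "planted-loop"))
    tm_rows.extend(decoy_tm_rows)

    mt_rows = []
    for m, g in zip(triad_mirnas, triad_targets):
        mt_rows.append((m, g, float(rng.uniform(55, 99))))
    for tf, m in zip(loop_tfs, loop_mirnas):
        mt_rows.append((m, tf, float(rng.uniform(55, 99))))
    mt_rows.extend(decoy_mt_rows)

    # Filler edges always hang off a non-DE miRNA, so they cannot complete a
    # triad or loop even when paired with a true DE gene.
    seen_tm = {(canonical_symbol(t), canonical_symbol(m, "mirna")) for t, m, _, _ in tm_rows}
    n_added = 0
    while n_added < cfg.n_filler_tf_edges and non_de_mirnas:
        tf = str(rng.choice(tf_symbols))
        m = str(rng.choice(non_de_mirnas))
        key = (canonical_symbol(tf), canonical_symbol(m, "mirna"))
        if key in seen_tm:
            continue
        seen_tm.add(key)
        tm_rows.append((tf, m, str(rng.choice(["Activation", "Repression", "Unknown"])), "filler"))
        n_added += 1

    seen_mt = {(canonical_symbol(m, "mirna"), canonical_symbol(g)) for m, g, _ in mt_rows}
    n_added = 0
    while n_added < cfg.n_filler_target_edges and non_de_mirnas:
        m = str(rng.choice(non_de_mirnas))
        g = str(rng.choice(non_tf_genes))
        key = (canonical_symbol(m, "mirna"), canonical_symbol(g))
        if key in seen_mt:
            continue
        seen_mt.add(key)
        mt_rows.append((m, g, float(rng.uniform(0, 100))))
        n_added += 1

    tables = RegPredictionTables.from_frames(
        pd.DataFrame(tm_rows, columns=["tf", "mirna", "action", "evidence"]),
        pd.DataFrame(mt_rows, columns=["mirna", "target", "score"]),
    )

    # --- expression studies ----------------------------------------------------
    def make_study(study_id: str, features: list[str], effects: dict[str, float], kind: str) -> ExpressionStudy:
        n = cfg.samples_per_group
        lo, hi = cfg.baseline_range
        baseline = rng.uniform(lo, hi, size=len(features))
        eff = np.array([effects.get(f, 0.0) for f in features])
        values = np.tile(baseline[:, None], (1, 2 * n)) + rng.normal(0.0, cfg.noise_sd, (len(features), 2 * n))
        values[:, :n] += eff[:, None]
        samples = [f"{study_id}_case_{i+1}" for i in range(n)] + [f"{study_id}_ctrl_{i+1}" for i in range(n)]
        design = {s: ("case" if i < n else "control") for i, s in enumerate(samples)}
        return ExpressionStudy(study_id=study_id, features=list(features), samples=samples,
                               values=values, design=design, feature_kind=kind)

    studies = [
        make_study(f"study{i+1}", gene_symbols, gene_fx, "mRNA") for i in range(cfg.n_studies)
    ]
    mirna_study = make_study("mirna_study", mirna_symbols, mirna_fx, "miRNA")

    # --- PPI graph: planted cliques over DE genes on a random background ------
    de_gene_list = sorted(de_gene_keys)
    if sum(cfg.planted_module_sizes) > len(de_gene_list):
        raise ConfigError("planted module sizes exceed the number of DE genes")
    if any(s < 4 for s in cfg.planted_module_sizes):
        raise ConfigError("planted modules must have >= 4 members")
    module_pool = list(rng.permutation(de_gene_list))
    modules = [frozenset(_take(module_pool, s, "DE genes for modules")) for s in cfg.planted_module_sizes]

    n_bg = min(cfg.ppi_n_background, len(non_tf_genes))
    bg_nodes = [canonical_symbol(g) for g in rng.choice(
        [g for g in non_tf_genes if canonical_symbol(g) not in de_gene_keys], size=n_bg, replace=False)]
    ppi_nodes = sorted(set(de_gene_list) | set(bg_nodes))
    ppi = nx.Graph()
    ppi.add_nodes_from(ppi_nodes)
    for i, u in enumerate(ppi_nodes):
        for v in ppi_nodes[i + 1:]:
            if rng.random() < cfg.ppi_edge_prob:
                ppi.add_edge(u, v)
    for mod in modules:
        members = sorted(mod)
        for i, u in enumerate(members):
            for v in members[i + 1:]:
                ppi.add_edge(u, v)

    truth = TruthRecord(
        true_degs=de_gene_keys,
        true_dems=de_mirna_keys,
        planted_triads=sorted(triads),
        planted_loops=sorted(loops),
        decoy_edges=decoys,
        planted_modules=modules,
        seed=int(seed),
    )
    truth.validate()
    return SyntheticDataset(studies=studies, mirna_study=mirna_study, tables=tables,
                            ppi=ppi, truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# Fixture round-tripping
# ---------------------------------------------------------------------------

def write_fixtures(dataset: SyntheticDataset, out_dir: str | Path) -> None:
    """Write every file in the formats the readers consume, plus truth TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for study in dataset.studies:
        write_expression_study(study, out / f"{study.study_id}.tsv", out / f"{study.study_id}.design.tsv")
    write_expression_study(dataset.mirna_study, out / "mirna_study.tsv", out / "mirna_study.design.tsv")
    write_prediction_tables(dataset.tables, out / "tf_mirna.tsv", out / "mirna_target.tsv")
    write_ppi_edges(dataset.ppi, out / "ppi.tsv")

    t = dataset.truth
    pd.DataFrame(sorted(t.true_degs.items()), columns=["gene", "effect"]).to_csv(
        out / "truth_degs.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(t.true_dems.items()), columns=["mirna", "effect"]).to_csv(
        out / "truth_dems.tsv", sep="\t", index=False)
    pd.DataFrame(t.planted_triads, columns=["tf", "mirna", "target"]).to_csv(
        out / "truth_triads.tsv", sep="\t", index=False)
    pd.DataFrame(t.planted_loops, columns=["tf", "mirna"]).to_csv(
        out / "truth_loops.tsv", sep="\t", index=False)
    pd.DataFrame(t.decoy_edges).to_csv(out / "truth_decoys.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(i + 1, ";".join(sorted(mod))) for i, mod in enumerate(t.planted_modules)],
        columns=["module", "members"],
    ).to_csv(out / "truth_modules.tsv", sep="\t", index=False)
    with open(out / "generator_config.yaml", "w") as fh:
        cfg = asdict(dataset.config)
        cfg["planted_module_sizes"] = list(cfg["planted_module_sizes"])
        cfg["baseline_range"] = list(cfg["baseline_range"])
        yaml.safe_dump({"seed": t.seed, **cfg}, fh, sort_keys=True)
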