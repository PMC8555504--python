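"""Curated regulatory evidence for mouse renal ischemia-reperfusion injury.

The records below are the published TF-miRNA feedback-loop evidence for the
renal IRI case/control screen: ChIP-seq-derived TF->miRNA binding sites (as
catalogued by TransmiR v2.0) paired with miRDB target-prediction scores for
the reciprocal miRNA->TF edge, plus the thirteen injury-regulated
transcription factors recovered by the DEG overlap in that system (all
up-regulated in injured kidney, as are the looped miRNAs).

They serve as a small real-data fixture: running the loop detector over
these tables must recover exactly the four published loops.
"""

from __future__ import annotations

import pandas as pd

from .dataio import RegPredictionTables, canonical_symbol
from .regnet import FeedbackLoop, detect_loops, filter_consistent_edges, overlap_tfs

#: Injury-regulated transcription factors (DEG overlap), all up-regulated.
RENAL_IRI_DE_TFS = (
    "Atf4", "Cebpb", "Egr1", "Egr2", "Fos", "Fosl1", "Fosl2",
    "Junb", "Mafk", "Nfil3", "Snai1", "Sox4", "Sox9",
)

#: (TF, miRNA, binding site, SRA run, miRNA sequence, miRDB target score)
FEEDBACK_LOOP_EVIDENCE = (
    ("Fosl2", "mir-155", "chr16:84703195-84703369 (score = 647)",
     "SRX187214", "UUAAUGCUAAUUGUGAUAGGGGU", 73),
    ("Fosl2", "mir-146a", "chr11:43377227-43377530 (score = 541)",
     "SRX187215", "UGAGAACUGAAUUCCAUGGGUU", 51),
    ("Mafk", "mir-25", "chr5:138165696-138165895 (score = 1000)",
     "SRX188829", "CAUUGCACUUGUCUCGGUCUGA", 71),
    ("Cebpb", "mir-155", "chr16:84712939-84713250 (score = 447)",
     "SRX2901279", "UUAAUGCUAAUUGUGAUAGGGGU", 88),
)


def reference_loop_tables() -> RegPredictionTables:
    """Prediction tables built from the curated loop evidence.

    The TF->miRNA rows are activating ChIP-seq edges; the miRNA->target rows
    list the reciprocal TF as a predicted target with its prediction score.
    """
    tm = pd.DataFrame(
        [(tf, m, "Activation", site) for tf, m, site, *_ in FEEDBACK_LOOP_EVIDENCE],
        columns=["tf", "mirna", "action", "evidence"],
    )
    mt = pd.DataFrame(
        [(m, tf, score) for tf, m, _, _, _, score in FEEDBACK_LOOP_EVIDENCE],
        columns=["mirna", "target", "score"],
    )
    return RegPredictionTables.from_frames(tm, mt)


def detect_reference_loops() -> list[FeedbackLoop]:
    """Run the real overlap/filter/loop code path over the curated evidence.

    All thirteen DE TFs and the looped miRNAs are up-regulated in injury, so
    the activating edges are sign-consistent and every reciprocal-target pair
    must come back as a loop.
    """
    tables = reference_loop_tables()
    deg_calls = {canonical_symbol(tf): "up" for tf in RENAL_IRI_DE_TFS}
    dem_calls = {
        canonical_symbol(m, "mirna"): "up"
        for _, m, *_ in FEEDBACK_LOOP_EVIDENCE
    }
    tf_set = overlap_tfs(deg_calls, tables, dem_calls)
    tf_edges, _ = filter_consistent_edges(tf_set, dem_calls, {}, tables)
    return detect_loops(tf_edges, tables, tf_set)
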