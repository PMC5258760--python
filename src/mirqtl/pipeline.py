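"""End-to-end orchestration: count libraries -> DE miRNAs -> targets ->
QTLs -> ranked candidate (miRNA, gene) pairs.

The stages are the library functions of the other modules; this module only
wires them together in the order the integrative analysis prescribes and is
what the CLI and the synthetic end-to-end runs use.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import de_calling, integration, sssl_qtl, synthetic_data, target_scoring


@dataclass
class FunnelResult:
    de_calls: list
    qtls: list
    hits: list
    candidates: list
    candidate_table: pd.DataFrame


def run_synthetic_funnel(
    config: synthetic_data.SimulationConfig,
    scheme: target_scoring.ScoringScheme | None = None,
    alpha: float = 0.05,
) -> tuple[FunnelResult, dict]:
    """Run the whole pipeline on one synthetic dataset.

    Returns the funnel result plus the generator truth tables (spiked
    miRNAs, planted QTL carriers, planted target pairs) for evaluation.
    """
    scheme = scheme or target_scoring.ScoringScheme()

    sim_counts = synthetic_data.simulate_counts(config)
    confirmed = de_calling.confirm_mirnas(sim_counts.counts)
    tpm = de_calling.tpm_normalize(confirmed)
    de_calls = []
    for contrast in de_calling.all_contrasts(confirmed.library_meta):
        de_calls.extend(de_calling.call_de(tpm, confirmed, contrast, alpha=alpha))
    de_mirnas = sorted({c.mirna_id for c in de_calls if c.is_de})

    panel = synthetic_data.simulate_sssl_panel(config)
    qtls = sssl_qtl.detect_qtls(
        panel.genotypes, panel.markers, panel.phenotypes, config.parent_id, alpha=alpha
    )

    targets = synthetic_data.simulate_annotation_and_targets(
        config, sim_counts.truth, panel.qtl_intervals,
        avoid_intervals=panel.carrier_segments,
    )
    mirna_seqs = dict(targets.mirna_records)
    de_with_seq = [(m, mirna_seqs[m]) for m in de_mirnas if m in mirna_seqs]
    hits = target_scoring.predict_targets(de_with_seq, targets.transcript_records, scheme)

    genes_by_id = {g.gene_id: g for g in targets.genes}
    joined = [(h, genes_by_id[h.gene_id]) for h in hits if h.gene_id in genes_by_id]
    pairs = integration.intersect_targets_with_qtls(joined, qtls)

    gene_profiles, gene_abundance = synthetic_data.simulate_expression_profiles(
        config, sim_counts.truth, targets.truth_pairs
    )
    mirna_profiles = synthetic_data.mirna_profiles_from_tpm(tpm)
    pairs = integration.attach_evidence(pairs, de_calls, mirna_profiles, gene_profiles)
    ranked = integration.rank_candidates(pairs, gene_abundance)

    truth = {
        "counts": sim_counts.truth,
        "panel": panel.truth,
        "targets": targets.truth_pairs,
        "qtl_intervals": panel.qtl_intervals,
    }
    result = FunnelResult(
        de_calls=de_calls,
        qtls=qtls,
        hits=hits,
        candidates=ranked,
        candidate_table=integration.candidate_table(ranked),
    )
    return result, truth
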