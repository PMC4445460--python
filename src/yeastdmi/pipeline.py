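"""Umbrella pipeline: simulation -> screen -> classify -> map -> annotate
-> growth, with single-seed determinism and logged provenance.

Stage-local seeds are derived from the configured seed by fixed offsets so
a rerun with the same seed reproduces every output table bitwise.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd

from yeastdmi import io as ydio
from yeastdmi import __version__
from yeastdmi.annot import call_nonsense, detect_trna_suppressor
from yeastdmi.bsamap import allele_frequencies, ascertain_markers, \
    detect_low_af_regions, detect_marker_deserts
from yeastdmi.screen import instances_from_tables, summarize_screen
from yeastdmi.simcross import (
    make_cross,
    simulate_bsa_counts,
    simulate_screen,
    simulate_spore_pool,
    simulate_tetrads,
    two_locus_case_model,
    yeast_genome,
)
from yeastdmi.tetradmodel import classify_segregation

log = logging.getLogger(__name__)

_SEED_OFFSETS = {"simulate": 1, "screen": 2, "classify": 3, "map": 4,
                 "annotate": 5, "growth": 6}


class StageError(RuntimeError):
    pass


def run_pipeline(config: "ydio.RunConfig") -> dict:
    """Execute the configured stages in order; returns artifact paths.

    Any stage failure raises :class:`StageError` naming the stage; outputs
    written before the failure are left in place.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = config.header_meta()
    artifacts: dict = {}
    state: dict = {}

    stage_fns = {
        "simulate": _stage_simulate,
        "screen": _stage_screen,
        "classify": _stage_classify,
        "map": _stage_map,
        "annotate": _stage_annotate,
        "growth": _stage_growth,
    }
    for stage in config.stages:
        if stage not in stage_fns:
            raise StageError(f"unknown stage {stage!r}")
    _check_stage_inputs(config)
    for stage in config.stages:
        log.info("stage %s (yeastdmi %s, seed %d)", stage, __version__, config.seed)
        try:
            stage_fns[stage](config, out, meta, state, artifacts)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
    return artifacts


def _check_stage_inputs(config) -> None:
    """Fail before any compute when a requested stage lacks its input."""
    simulated = "simulate" in config.stages
    needs = {
        "screen": ("screen_table", "parents"),
        "map": ("counts",),
    }
    for stage, keys in needs.items():
        if stage in config.stages and not simulated:
            for key in keys:
                if key not in config.paths:
                    raise StageError(
                        f"stage {stage!r} requested without 'simulate' and no "
                        f"path.{key} configured"
                    )


def _stage_seed(config, stage: str) -> int:
    return (int(config.seed) * 7 + _SEED_OFFSETS[stage]) % (2**31)


def _stage_simulate(config, out, meta, state, artifacts) -> None:
    seed = _stage_seed(config, "simulate")
    screen_table, parents, labels = simulate_screen(
        n_crosses=config.n_crosses,
        n_conditions=config.n_conditions,
        tetrads_per_instance=config.tetrads_per_instance,
        seed=seed,
    )
    ydio.write_table(screen_table, out / "screen_table.tsv", meta=meta)
    ydio.write_table(parents, out / "parents.tsv", meta=meta)
    ydio.write_table(labels, out / "screen_labels.tsv", meta=meta)
    state["screen_table"], state["parents"] = screen_table, parents

    # focal two-locus cross: tetrads, inviable pool, pooled counts
    # (1 marker/kb: the density needed to resolve the rescuer-side desert)
    genome = yeast_genome(marker_spacing_bp=1000)
    model = two_locus_case_model()
    design = make_cross(genome, model, seed=seed)
    rng = np.random.default_rng(seed + 1)
    tetrads = simulate_tetrads(design, 40, rng)
    condition = sorted(model.conditions)[0]
    counts = Counter(t.n_viable(condition) for t in tetrads)
    tet_df = pd.DataFrame(
        sorted(counts.items(), reverse=True), columns=["viable_count", "n_tetrads"]
    )
    ydio.write_table(tet_df, out / "tetrad_counts.tsv", meta=meta)
    state["tetrad_counts"] = dict(counts)

    pool = simulate_spore_pool(design, condition, config.pool_size,
                               keep="inviable", rng=rng)
    track = simulate_bsa_counts(pool, config.coverage, config.error_rate, rng)
    ydio.write_counts_table(track, out / "pool_counts.tsv", meta=meta)
    state["counts"] = track
    state["design"] = design
    ydio.write_table(design.marker_table, out / "markers.tsv", meta=meta)
    artifacts.update(
        screen_table=out / "screen_table.tsv", parents=out / "parents.tsv",
        labels=out / "screen_labels.tsv", tetrad_counts=out / "tetrad_counts.tsv",
        pool_counts=out / "pool_counts.tsv", markers=out / "markers.tsv",
    )


def _stage_screen(config, out, meta, state, artifacts) -> None:
    if "screen_table" not in state:
        state["screen_table"] = ydio.read_table(config.paths["screen_table"])
        state["parents"] = ydio.read_table(config.paths["parents"])
    instances = instances_from_tables(state["screen_table"], state["parents"])
    summary = summarize_screen(
        instances,
        epistasis_threshold=config.epistasis_threshold,
        severe_threshold=config.severe_threshold,
    )
    ydio.write_table(summary.per_instance, out / "screen_instances.tsv", meta=meta)
    matrix = summary.matrix.fillna("excluded")
    ydio.write_table(matrix.reset_index(), out / "screen_matrix.tsv", meta=meta)
    artifacts.update(screen_instances=out / "screen_instances.tsv",
                     screen_matrix=out / "screen_matrix.tsv")
    state["summary"] = summary


def _stage_classify(config, out, meta, state, artifacts) -> None:
    if "tetrad_counts" not in state:
        state["tetrad_counts"] = ydio.read_tetrad_counts(
            config.paths.get("tetrad_counts", out / "tetrad_counts.tsv")
        )
    call = classify_segregation(
        state["tetrad_counts"],
        ["none", "two_locus_unlinked", "two_locus_linked", "complex"],
    )
    payload = {
        "best_model": call.best_model,
        "fit_pvalue": call.fit_pvalue,
        "r_hat": call.r_hat,
        "log_likelihoods": call.log_likelihoods,
        "bic": call.bic,
        "seed": config.seed,
    }
    path = out / "segregation_call.json"
    path.write_text(json.dumps(payload, indent=2))
    artifacts["segregation_call"] = path
    state["segregation_call"] = call


def _stage_map(config, out, meta, state, artifacts) -> None:
    if "counts" not in state:
        state["counts"] = ydio.read_counts_table(config.paths["counts"])
    called = ascertain_markers(state["counts"])
    track = allele_frequencies(called, min_depth=config.min_depth)
    ydio.write_table(track, out / "allele_frequencies.tsv", meta=meta)
    regions = detect_low_af_regions(track, af_threshold=config.af_threshold,
                                    min_run=config.min_run)
    if "design" in state:
        regions += detect_marker_deserts(track, state["design"].genome)
    ydio.write_regions(regions, out / "regions.bed", out / "regions.tsv", meta=meta)
    artifacts.update(allele_frequencies=out / "allele_frequencies.tsv",
                     regions_bed=out / "regions.bed", regions=out / "regions.tsv")
    state["regions"] = regions


def _stage_annotate(config, out, meta, state, artifacts) -> None:
    # worked example: premature stop in codon 39 plus the suppressor anticodon
    orf = _demo_orf()
    calls = call_nonsense(orf, [(115, "C", "T")], gene_id="resp_gene")
    sup = detect_trna_suppressor("GTA", "TTA", trna_id="tY_sup")
    rows = [
        (c.gene_id, c.codon_index, c.orf_nt_pos, c.ref_codon, c.alt_codon,
         c.stop_class)
        for c in calls
    ]
    df = pd.DataFrame(rows, columns=["gene_id", "codon_index", "orf_nt_pos",
                                     "ref_codon", "alt_codon", "stop_class"])
    ydio.write_table(df, out / "nonsense_calls.tsv", meta=meta)
    sup_df = pd.DataFrame(
        [(sup.trna_id, sup.anticodon_before, sup.anticodon_after,
          sup.suppressed_stop)] if sup else [],
        columns=["trna_id", "anticodon_before", "anticodon_after",
                 "suppressed_stop"],
    )
    ydio.write_table(sup_df, out / "suppressor_calls.tsv", meta=meta)
    artifacts.update(nonsense_calls=out / "nonsense_calls.tsv",
                     suppressor_calls=out / "suppressor_calls.tsv")


def _stage_growth(config, out, meta, state, artifacts) -> None:
    from yeastdmi.growth import fit_growth_rate, growth_variation
    from yeastdmi.simcross import simulate_growth_curve

    rng = np.random.default_rng(_stage_seed(config, "growth"))
    times = np.arange(0, 24.01, 1 / 6)
    rows = []
    for strain, (r_ctrl, r_sup) in {"strainA": (0.50, 0.386),
                                    "strainB": (0.45, 0.45)}.items():
        rates = {"SUP": [], "Ctrl": []}
        for plasmid, rate in (("SUP", r_sup), ("Ctrl", r_ctrl)):
            for rep in range(6):
                curve = simulate_growth_curve(rate, 2.0, 1.2, 0.005, times, rng,
                                              strain=strain, plasmid=plasmid,
                                              well_id=f"{strain}_{plasmid}_{rep}")
                rates[plasmid].append(fit_growth_rate(curve))
        comp = growth_variation(rates["SUP"], rates["Ctrl"], strain=strain,
                                condition="rich_medium")
        rows.append(vars(comp))
    ydio.write_table(pd.DataFrame(rows), out / "growth_comparisons.tsv", meta=meta)
    artifacts["growth_comparisons"] = out / "growth_comparisons.tsv"


def _demo_orf(n_codons: int = 120) -> str:
    """Synthetic in-frame ORF whose codon 39 is CAA; single terminal stop."""
    body = ["GCT"] * (n_codons - 2)  # alanine filler
    body[38 - 1] = "CAA"             # codon 39 overall (after ATG)
    return "ATG" + "".join(body) + "TAA"
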