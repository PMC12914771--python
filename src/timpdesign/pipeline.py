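"""End-to-end orchestration: enrich -> train -> design -> kinetics.

These functions tie the stages together the way the examples/ scripts use
them: plain functions over in-memory objects, with optional file output
(TSV/JSON only).  Every output embeds the seeds that produced it, so reruns
on identical inputs are byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import synthetic
from .design import SpaceMode, rank_candidates, reports_to_frame, top_k_fully_mutated
from .enrichment import (
    EnrichmentRecord,
    GateCountTable,
    Stringency,
    TrainingExample,
    build_training_table,
    count_reads_fasta,
    enrichment_ratios,
    records_to_frame,
    write_enrichment_tsv,
)
from .kinetics import KiFitResult, fit_ki, fold_changes
from .model import (
    EnsembleModel,
    HyperParams,
    evaluate,
    grid_search,
    split_by_depth,
    train_ensemble,
)
from .variant_space import ReferenceScheme, mutation_count_inventory

logger = logging.getLogger("timpdesign")


@dataclass
class EnrichmentResult:
    records: list[EnrichmentRecord]
    examples: list[TrainingExample]
    excluded: dict[str, int]
    inventory: dict[int, int]


def run_enrich(
    presort: GateCountTable,
    gate: GateCountTable,
    scheme: ReferenceScheme,
    out_dir: str | Path | None = None,
    pseudocount: float = 0.0,
    min_count: int = 1,
) -> EnrichmentResult:
    """Frequencies -> NF -> ER -> training labels for one sorted fraction."""
    records, excluded = enrichment_ratios(
        presort, gate, scheme, pseudocount=pseudocount, min_count=min_count
    )
    examples = build_training_table(records)
    inventory = mutation_count_inventory((r.signature for r in records), scheme)
    logger.info(
        "%s: %d variants (excluded %s); by mutation count %s",
        gate.gate, len(records), excluded, inventory,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_enrichment_tsv(records, out_dir / f"enrichment_{gate.gate}.tsv")
        (out_dir / f"enrichment_{gate.gate}.json").write_text(
            json.dumps(
                {
                    "gate": str(gate.gate),
                    "n_variants": len(records),
                    "excluded": excluded,
                    "mutation_count_inventory": inventory,
                    "rejections_presort": presort.rejection_stats,
                    "rejections_gate": gate.rejection_stats,
                },
                indent=2,
                sort_keys=True,
            )
        )
    return EnrichmentResult(records, examples, excluded, inventory)


def run_enrich_fasta(
    presort_fasta: str | Path,
    gate_fasta: str | Path,
    gate_label,
    scheme: ReferenceScheme,
    **kwargs,
) -> EnrichmentResult:
    """As :func:`run_enrich`, counting reads from FASTA gate files first."""
    from .enrichment import PRESORT

    presort = count_reads_fasta(presort_fasta, PRESORT, scheme)
    gate = count_reads_fasta(gate_fasta, gate_label, scheme)
    return run_enrich(presort, gate, scheme, **kwargs)


@dataclass
class TrainResult:
    model: EnsembleModel
    hyperparams: HyperParams
    val_pearson: float
    test_pearson: float
    leaderboard: pd.DataFrame | None = None


def run_train(
    examples: Sequence[TrainingExample],
    scheme: ReferenceScheme,
    hp: HyperParams | None = None,
    grid: dict[str, tuple] | None = None,
    base_seed: int = 0,
    n_members: int = 10,
    out_dir: str | Path | None = None,
) -> TrainResult:
    """Train the ensemble on the depth split; optionally grid-search first.

    With ``hp`` given, trains that single configuration; with ``grid`` given,
    runs the validation-Pearson grid search and keeps the winner.
    """
    split = split_by_depth(examples)
    leaderboard = None
    if grid is not None:
        best_hp, model, leaderboard = grid_search(
            examples, scheme, grid=grid, base_seed=base_seed, n_members=n_members
        )
    else:
        best_hp = hp if hp is not None else HyperParams(base_seed=base_seed)
        best_hp = dataclasses.replace(best_hp, base_seed=base_seed)
        model = train_ensemble(split.train, best_hp, scheme, n_members=n_members)
    val_r, _, _ = evaluate(model, split.val)
    test_r, _, _ = evaluate(model, split.test)
    logger.info("trained %s: val r=%.3f test r=%.3f", best_hp, val_r, test_r)
    if out_dir is not None:
        out_dir = Path(out_dir)
        model.save(out_dir / "model")
        if leaderboard is not None:
            leaderboard.to_csv(out_dir / "leaderboard.tsv", sep="\t", index=False)
        (out_dir / "train_metrics.json").write_text(
            json.dumps(
                {
                    "hyperparams": dataclasses.asdict(best_hp),
                    "val_pearson": val_r,
                    "test_pearson": test_r,
                    "n_examples": len(examples),
                },
                indent=2,
                sort_keys=True,
            )
        )
    return TrainResult(model, best_hp, val_r, test_r, leaderboard)


def run_design(
    primary_model: EnsembleModel,
    off_target_models: Mapping[str, EnsembleModel],
    scheme: ReferenceScheme,
    k: int = 5,
    mode: SpaceMode | None = None,
    top_k_sample_n: int | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
):
    """Top-k fully mutated candidates for the primary target, ranked off-target."""
    if mode is None:
        mode = SpaceMode.sampled(n=1_000_000, seed=seed)
    top = top_k_fully_mutated(
        primary_model, scheme, k=k, sample_n=top_k_sample_n, seed=seed
    )
    reports = rank_candidates(
        [sig for sig, _ in top], primary_model, off_target_models, scheme, mode
    )
    frame = reports_to_frame(reports)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out_dir / "candidates.tsv", sep="\t", index=False, float_format="%.6g")
        (out_dir / "design_meta.json").write_text(
            json.dumps(
                {"k": k, "seed": seed, "space_mode": dataclasses.asdict(mode),
                 "top_k_sample_n": top_k_sample_n},
                indent=2,
                sort_keys=True,
            )
        )
    return reports


def run_kinetics(
    curves_per_enzyme: Mapping[str, Sequence],
    s_um: float,
    km_um: Mapping[str, float],
    reference: str,
    out_dir: str | Path | None = None,
) -> tuple[dict[str, KiFitResult], "object"]:
    """Fit Ki per enzyme from replicate curves and build the selectivity profile."""
    fits = {
        enzyme: fit_ki(curves, s_um, km_um[enzyme])
        for enzyme, curves in curves_per_enzyme.items()
    }
    profile = fold_changes({e: f.ki_nm for e, f in fits.items()}, reference)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "kinetics.json").write_text(
            json.dumps(
                {
                    enzyme: {
                        "ki_nm": f.ki_nm,
                        "ki_sd_nm": f.ki_sd_nm,
                        "kiapp_nm": f.kiapp_nm,
                        "fold_change": profile.fold_change[enzyme],
                    }
                    for enzyme, f in fits.items()
                },
                indent=2,
                sort_keys=True,
            )
        )
    return fits, profile


# ---------------------------------------------------------------------------
# The full synthetic pipeline (the package's main end-to-end computation)
# ---------------------------------------------------------------------------

@dataclass
class SyntheticPipelineResult:
    scheme: ReferenceScheme
    config: synthetic.SortSimulationConfig
    n_variants: int
    test_pearson_measured: float
    test_pearson_true: float
    top_candidates: list[tuple[str, float]]
    reports: list
    top_true_energy_quantile: float
    models: dict[str, EnsembleModel]


def run_synthetic_pipeline(
    seed: int = 0,
    config: synthetic.SortSimulationConfig | None = None,
    hp: HyperParams | None = None,
    k: int = 5,
    top_k_sample_n: int = 200_000,
    percentile_n: int = 1_000_000,
    n_members: int = 10,
    energy_reference_n: int = 100_000,
    out_dir: str | Path | None = None,
) -> SyntheticPipelineResult:
    """Generate, enrich, train, and design against two planted landscapes.

    Target A is the primary (high-affinity) objective and target B the
    off-target; both are independent additive landscapes over the same
    scheme.  Returns test-set correlations against both the measured and the
    ground-truth log2 ER, the designed candidates with off-target
    percentiles, and the quantile of the top candidate's true A-energy in a
    uniform reference sample of the whole space (0 = best possible).
    """
    scheme = synthetic.make_reference_scheme()
    if config is None:
        config = synthetic.SortSimulationConfig(seed=seed)
    landscape_a = synthetic.make_landscape(scheme, seed=seed + 11)
    landscape_b = synthetic.make_landscape(scheme, seed=seed + 12)
    library = synthetic.sample_library(scheme, config)

    models: dict[str, EnsembleModel] = {}
    pearsons: dict[str, tuple[float, float]] = {}
    for name, landscape, offset in (("A", landscape_a, 0), ("B", landscape_b, 1)):
        tables = synthetic.simulate_sort_counts(
            library,
            landscape,
            dataclasses.replace(config, seed=config.seed + 100 * (offset + 1)),
            target=name,
        )
        enr = run_enrich(
            tables[Stringency.PRESORT], tables[Stringency.HIGH], scheme,
            out_dir=out_dir,
        )
        train_res = run_train(
            enr.examples, scheme, hp=hp, base_seed=seed + 1000 * (offset + 1),
            n_members=n_members,
            out_dir=None,
        )
        models[name] = train_res.model
        split = split_by_depth(enr.examples)
        test_sigs = [e.signature for e in split.test]
        predicted = train_res.model.predict_signatures(test_sigs)
        truth = synthetic.true_log2_er(test_sigs, landscape, config)
        from .model import pearson as _pearson

        pearsons[name] = (train_res.test_pearson, _pearson(predicted, truth))

    top = top_k_fully_mutated(
        models["A"], scheme, k=k, sample_n=top_k_sample_n, seed=seed + 21
    )
    mode = SpaceMode.sampled(n=percentile_n, seed=seed + 22)
    reports = rank_candidates(
        [sig for sig, _ in top], models["A"], {"B": models["B"]}, scheme, mode,
        primary_name="A",
    )

    # Where does the top candidate's *true* A-energy sit in the whole space?
    rng_ref = np.random.default_rng(seed + 23)
    from .variant_space import sample_variant_space

    reference = sample_variant_space(scheme, energy_reference_n, rng_ref)
    ref_energies = landscape_a.energy_batch(reference)
    top_energy = landscape_a.energy(top[0][0])
    quantile = float((ref_energies > top_energy).mean())

    result = SyntheticPipelineResult(
        scheme=scheme,
        config=config,
        n_variants=len(library),
        test_pearson_measured=pearsons["A"][0],
        test_pearson_true=pearsons["A"][1],
        top_candidates=top,
        reports=reports,
        top_true_energy_quantile=quantile,
        models=models,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        reports_to_frame(reports).to_csv(
            out_dir / "candidates.tsv", sep="\t", index=False, float_format="%.6g"
        )
        (out_dir / "pipeline_summary.json").write_text(
            json.dumps(
                {
                    "seed": seed,
                    "n_variants": result.n_variants,
                    "test_pearson_measured": result.test_pearson_measured,
                    "test_pearson_true": result.test_pearson_true,
                    "top_candidate": top[0][0],
                    "top_true_energy_quantile": quantile,
                },
                indent=2,
                sort_keys=True,
            )
        )
    return result
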