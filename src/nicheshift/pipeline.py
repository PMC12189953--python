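"""End-to-end pipeline.

Executes the seven-stage workflow — (i) occurrence QC, (ii) variable
selection, (iii) vessel/MPA/EEZ layers, (iv) ensemble niche modeling,
(v) scenario projection and range-change accounting, (vi) hotspot
identification and protection gaps, (vii) shipping co-occurrence — on a
synthetic world whose ground truth is known, writing every artifact plus a
checksummed manifest.  All randomness derives from the single root seed, so
a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nio
from .change import (
    RangeChange,
    latitudinal_density,
    net_change_map,
    range_change,
    stack_richness,
)
from .config import RunConfig
from .ensemble import (
    EnsembleModel,
    binarize,
    build_ensemble,
    build_training_table,
    evaluate_members,
    predict_map,
    sample_pseudoabsences,
    split_train_test,
)
from .grid import EnvStack, RasterLayer, ZoneLayers
from .metrics import roc_auc, tss_at_threshold
from .occurrences import OccurrenceSet, run_qc
from .overlay import (
    HotspotMap,
    OverlapReport,
    cooccurrence_summary,
    hotspot_map,
    overlap_report,
    shipping_transform,
)
from .synthetic import (
    NicheParams,
    apply_land_mask,
    default_species,
    generate_env_stack,
    generate_shipping,
    generate_zones,
    sample_occurrences,
    true_suitability,
)
from .variables import (
    mean_importance,
    pearson_matrix,
    screen_importances,
    select_variables,
)


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0]) % (2**31)


@dataclass
class SpeciesResult:
    """Everything the pipeline computed for one species."""

    species_id: str
    occurrences: OccurrenceSet
    selected_variables: list[str]
    evaluations: pd.DataFrame
    ensemble: EnsembleModel
    ensemble_auc: float
    ensemble_tss: float
    suitability: dict[str, RasterLayer]  # per scenario tag, continuous
    binary: dict[str, RasterLayer]       # per scenario tag, thresholded
    range_changes: dict[str, RangeChange]
    truth: RasterLayer | None = None


@dataclass
class PipelineResult:
    config: RunConfig
    stacks: dict[str, EnvStack]
    zones: ZoneLayers
    shipping: RasterLayer
    species: dict[str, SpeciesResult]
    richness: dict[str, RasterLayer]
    net_change: dict[str, RasterLayer]
    hotspots: dict[str, HotspotMap]
    overlaps: dict[str, OverlapReport]
    cooccurrence: dict[str, pd.DataFrame]
    out_dir: Path | None = None


def fit_species(
    species_id: str,
    stack: EnvStack,
    occ: OccurrenceSet,
    variables: list[str],
    config: RunConfig,
    seed: int,
) -> tuple[EnsembleModel, pd.DataFrame]:
    """Pseudoabsences → folds → members → TSS-gated weighted ensemble."""
    ss = np.random.SeedSequence(seed)
    pa_seed, fold_seed, member_seed = ss.spawn(3)
    pa_sets = sample_pseudoabsences(
        stack, occ, n=config.n_pseudoabsences, n_reps=config.n_pa_reps,
        seed=_seed_int(pa_seed),
    )
    members = []
    eval_rows = []
    fold_children = fold_seed.spawn(len(pa_sets))
    member_children = member_seed.spawn(len(pa_sets))
    for pa, f_ss, m_ss in zip(pa_sets, fold_children, member_children):
        table = build_training_table(stack, occ, pa, variables)
        folds = split_train_test(
            table["label"].to_numpy(), train_fraction=config.train_fraction,
            n_folds=config.n_folds, seed=_seed_int(f_ss),
        )
        reps_members, _full = evaluate_members(
            table, folds, pa.rep_index, config.algorithms, variables,
            seed=_seed_int(m_ss),
        )
        members.extend(reps_members)
        for _tr, te in folds:
            if te.size:
                eval_rows.append(table.iloc[te])
    eval_table = pd.concat(eval_rows, ignore_index=True)
    ensemble = build_ensemble(members, eval_table, tss_min=config.tss_min)
    ens_scores = ensemble.predict(eval_table[ensemble.variables])
    ens_labels = eval_table["label"].to_numpy()
    ens_auc = roc_auc(ens_scores, ens_labels)
    ens_tss = tss_at_threshold(ens_scores, ens_labels, ensemble.threshold)
    evals = pd.DataFrame([{
        "species": species_id,
        "algorithm": m.record.algorithm_id,
        "pa_rep": m.record.pa_rep,
        "fold": m.record.fold,
        "tss": m.record.tss,
        "roc_auc": m.record.roc_auc,
        "threshold": m.record.optimal_threshold,
    } for m in members])
    return ensemble, evals, ens_auc, ens_tss


def select_species_variables(
    stack: EnvStack,
    occ: OccurrenceSet,
    config: RunConfig,
    seed: int,
) -> tuple[list[str], pd.Series, pd.DataFrame]:
    """Importance screening + correlation filter on presence/PA cells."""
    ss = np.random.SeedSequence(seed)
    pa_seed, screen_seed = ss.spawn(2)
    pa = sample_pseudoabsences(stack, occ, n=config.n_pseudoabsences,
                               n_reps=1, seed=_seed_int(pa_seed))[0]
    table = build_training_table(stack, occ, pa, stack.names)
    imp_long = screen_importances(
        table[stack.names], table["label"].to_numpy(),
        algorithms=config.algorithms, seed=_seed_int(screen_seed),
    )
    imp = mean_importance(imp_long)
    rows, cols, inside = stack.spec.cells_of(
        table["lon"].to_numpy(), table["lat"].to_numpy())
    cor = pearson_matrix(stack, rows[inside], cols[inside], stack.names)
    selected = select_variables(imp, cor, r_max=config.r_max, k=config.k_variables)
    return selected, imp, cor


def run_pipeline(
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
    species: list[NicheParams] | None = None,
    write: bool = True,
) -> PipelineResult:
    """Run the full synthetic-world analysis.

    Set ``write=False`` (or ``out_dir=None``) to keep everything in memory.
    """
    config = config or RunConfig()
    spec = config.world.grid()
    if species is None:
        species = default_species(config.world.n_species)

    root = np.random.SeedSequence(config.seed)
    env_ss, zone_ss, ship_ss, occ_ss, qc_ss, sel_ss, sdm_ss = root.spawn(7)

    # --- world ------------------------------------------------------------
    zones = generate_zones(spec, mpa_fraction=config.mpa_fraction,
                           n_eez=config.n_eez, seed=_seed_int(zone_ss))
    raw_stacks = generate_env_stack(spec, n_vars=config.world.n_vars,
                                    warming_deltas=config.scenarios,
                                    seed=_seed_int(env_ss))
    stacks = {tag: apply_land_mask(s, zones.land) for tag, s in raw_stacks.items()}
    shipping = generate_shipping(spec, n_lanes=config.n_shipping_lanes,
                                 seed=_seed_int(ship_ss), land=zones.land)
    current = stacks["current"]
    scenario_tags = [t for t in stacks if t != "current"]

    # --- per species ------------------------------------------------------
    occ_children = occ_ss.spawn(len(species))
    qc_children = qc_ss.spawn(len(species))
    sel_children = sel_ss.spawn(len(species))
    sdm_children = sdm_ss.spawn(len(species))
    results: dict[str, SpeciesResult] = {}
    for sp, o_ss, q_ss, s_ss, m_ss in zip(
            species, occ_children, qc_children, sel_children, sdm_children):
        truth = true_suitability(sp, current)
        occ_raw = sample_occurrences(truth, config.n_occurrences,
                                     error_rates=config.error_rates,
                                     seed=_seed_int(o_ss),
                                     species_id=sp.species_id)
        occ = run_qc(occ_raw, zones.land, min_dist_km=config.min_dist_km,
                     precision_decimals=config.precision_decimals,
                     seed=_seed_int(q_ss))
        selected, _imp, _cor = select_species_variables(
            current, occ, config, seed=_seed_int(s_ss))
        ensemble, evals, ens_auc, ens_tss = fit_species(
            sp.species_id, current, occ, selected, config, seed=_seed_int(m_ss))
        suit = {tag: predict_map(ensemble, stacks[tag]) for tag in stacks}
        bins = {tag: binarize(m, ensemble.threshold) for tag, m in suit.items()}
        changes = {tag: range_change(bins["current"], bins[tag])
                   for tag in scenario_tags}
        results[sp.species_id] = SpeciesResult(
            species_id=sp.species_id, occurrences=occ,
            selected_variables=selected, evaluations=evals, ensemble=ensemble,
            ensemble_auc=ens_auc, ensemble_tss=ens_tss,
            suitability=suit, binary=bins, range_changes=changes, truth=truth,
        )

    # --- community summaries ----------------------------------------------
    richness = {
        tag: stack_richness({sid: r.binary[tag] for sid, r in results.items()},
                            scenario_tag=tag)
        for tag in stacks
    }
    net_change = {
        tag: net_change_map(
            {sid: (r.binary["current"], r.binary[tag]) for sid, r in results.items()},
            scenario_tag=tag)
        for tag in scenario_tags
    }
    # hotspots are a multi-species construct; skipped for single-species runs
    hotspots = {}
    if len(results) >= 2:
        hotspots = {
            tag: hotspot_map({sid: r.suitability[tag] for sid, r in results.items()},
                             cutoff=config.hotspot_cutoff, scenario_tag=tag)
            for tag in stacks
        }
    overlaps = {tag: overlap_report(h, zones) for tag, h in hotspots.items()}
    _sqrt, high_ship = shipping_transform(shipping)
    cooccurrence = {tag: cooccurrence_summary(net_change[tag], high_ship, zones)
                    for tag in scenario_tags}

    result = PipelineResult(
        config=config, stacks=stacks, zones=zones, shipping=shipping,
        species=results, richness=richness, net_change=net_change,
        hotspots=hotspots, overlaps=overlaps, cooccurrence=cooccurrence,
    )
    if write and out_dir is not None:
        result.out_dir = write_artifacts(result, Path(out_dir))
    return result


# ---------------------------------------------------------------------------
# Artifact writing

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_artifacts(result: PipelineResult, out_dir: Path) -> Path:
    """Write CSV/JSON/raster artifacts and a checksummed manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    cfg.to_yaml(out_dir / "config.yaml")

    nio.write_raster(result.zones.land, out_dir / "land.asc")
    nio.write_raster(result.zones.mpa, out_dir / "mpa.asc")
    nio.write_raster(result.zones.eez, out_dir / "eez.asc")
    nio.write_raster(result.shipping, out_dir / "shipping.asc")

    evals = pd.concat([r.evaluations for r in result.species.values()],
                      ignore_index=True)
    evals.to_csv(out_dir / "evaluations.csv", index=False)

    sel = {sid: r.selected_variables for sid, r in result.species.items()}
    (out_dir / "selected_variables.json").write_text(json.dumps(sel, indent=1))

    rc_rows = []
    for sid, r in result.species.items():
        nio.write_occurrences(r.occurrences, out_dir / f"occurrences_{sid}.csv")
        nio.write_qc_report(r.occurrences, out_dir / f"qc_{sid}.json")
        for tag, ch in r.range_changes.items():
            rc_rows.append({"species": sid, "scenario": tag, **asdict(ch)})
        latitudinal_density(r.binary["current"]).to_csv(
            out_dir / f"latdensity_{sid}.csv", index=False)
    pd.DataFrame(rc_rows).to_csv(out_dir / "range_change.csv", index=False)

    maps_dir = out_dir / "maps"
    maps_dir.mkdir(exist_ok=True)
    for sid, r in result.species.items():
        for tag in r.suitability:
            nio.write_raster(r.suitability[tag], maps_dir / f"suit_{sid}_{tag}.asc")
            nio.write_raster(r.binary[tag], maps_dir / f"bin_{sid}_{tag}.asc")
    for tag, lyr in result.richness.items():
        nio.write_raster(lyr, maps_dir / f"richness_{tag}.asc")
    for tag, lyr in result.net_change.items():
        nio.write_raster(lyr, maps_dir / f"netchange_{tag}.asc")
    for tag, h in result.hotspots.items():
        nio.write_raster(h.hotspot_mask, maps_dir / f"hotspots_{tag}.asc")

    overlap_json = {}
    for tag, rep in result.overlaps.items():
        rep.per_zone.to_csv(out_dir / f"overlap_zones_{tag}.csv", index=False)
        overlap_json[tag] = {
            "total_km2": rep.total_km2,
            "protected_km2": rep.protected_km2,
            "unprotected_km2": rep.unprotected_km2,
            "pct_protected": rep.pct_protected,
        }
    (out_dir / "overlap.json").write_text(json.dumps(overlap_json, indent=1))
    for tag, table in result.cooccurrence.items():
        table.to_csv(out_dir / f"cooccurrence_{tag}.csv", index=False)

    files = sorted(p for p in out_dir.rglob("*")
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "seed": cfg.seed,
        "config": asdict(cfg),
        "checksums": {str(p.relative_to(out_dir)): _sha256(p) for p in files},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out_dir
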