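"""A bundled synthetic study and the stage runners the CLI chains together.

The demo study emulates the structure of a GRK-selectivity screen at desk
scale: two synthetic GPCR–arrestin pairs measured in six conditions
(parental Control + empty vector; quadruple-GRK-knockout + empty vector;
knockout + GRK2/3/5/6 rescue), five ligand concentrations plus vehicle,
matched mock-labelled wells, four independent replicates.  ``demoR1`` is
regulated by GRK2/3 only and pre-couples in the GRK2 condition; ``demoR2``
is regulated by all four kinases.  A segment set with group-dependent motif
placement and a DMR experiment complete the bundle.

Every stage runner reads and writes the documented file formats, so the
pipeline is closed: simulate → reduce → fit → classify → motifs → report.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .doseresponse import (
    ConcentrationSeries,
    dmr_auc,
    dmr_concentration_effect,
    fit_concentration_response,
    gate_functional_recruitment,
)
from .io import (
    plate_to_welltraces,
    read_plate_csv,
    read_segments_fasta,
    write_plate_csv,
    write_segments_fasta,
)
from .motifs import build_contingency, fisher_exact, group_summary, scan_segment
from .reduction import baseline_bars, per_replicate_baselines, reduce_plate
from .selectivity import REFERENCE_CONDITION, call_precoupling, classify_matrix
from .synth import (
    AssayDesign,
    ConditionTruth,
    DmrTruth,
    generate_bret_dataset,
    generate_dmr_dataset,
    generate_segment_set,
    wells_to_table,
)

DEMO_CONCENTRATIONS = (0.0, 1e-10, 1e-9, 1e-8, 1e-7, 1e-6)

_BASE = dict(basal_ratio=0.5, mock_ratio=0.1, noise_cv=0.03, log_ec50=-8.0,
             response_tau_s=30.0)

#: per pair: condition suffix -> ConditionTruth keyword overrides
DEMO_PAIRS = {
    "demoR1": {  # GRK2/3-regulated; pre-couples when GRK2 is overexpressed
        "Control+EV": dict(top_fold=1.5),
        "dQ-GRK+EV": dict(top_fold=1.0),
        "dQ-GRK+GRK2": dict(top_fold=1.5, precoupling_factor=1.3),
        "dQ-GRK+GRK3": dict(top_fold=1.45),
        "dQ-GRK+GRK5": dict(top_fold=1.0),
        "dQ-GRK+GRK6": dict(top_fold=1.0),
    },
    "demoR2": {  # regulated by any tested kinase
        "Control+EV": dict(top_fold=1.6),
        "dQ-GRK+EV": dict(top_fold=1.0),
        "dQ-GRK+GRK2": dict(top_fold=1.55),
        "dQ-GRK+GRK3": dict(top_fold=1.5),
        "dQ-GRK+GRK5": dict(top_fold=1.4),
        "dQ-GRK+GRK6": dict(top_fold=1.45),
    },
}


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=2) + "\n")


def run_simulate(out_dir, seed: int, config: RunConfig | None = None) -> dict:
    """Write the bundled synthetic study (plate CSV, DMR CSV, FASTA, truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or RunConfig()
    ss = np.random.SeedSequence(seed)
    plate_seed, seg_seed, dmr_seed = (int(s.generate_state(1)[0] >> 1) for s in ss.spawn(3))

    all_wells = []
    truth_doc = {"seed": seed, "pairs": {}}
    for p_idx, (pair, conditions) in enumerate(sorted(DEMO_PAIRS.items())):
        labels = tuple(f"{pair}:{c}" for c in conditions)
        design = AssayDesign(
            conditions=labels,
            concentrations=DEMO_CONCENTRATIONS,
            n_replicates=4,
        )
        truths = {
            f"{pair}:{c}": ConditionTruth(**{**_BASE, **kw})
            for c, kw in conditions.items()
        }
        wells = generate_bret_dataset(design, truths, seed=plate_seed + p_idx)
        for w in wells:
            w.meta = dataclasses.replace(w.meta, well_id=f"{pair}-{w.meta.well_id}",
                                         receptor=pair, arrestin="barr2")
        all_wells.extend(wells)
        truth_doc["pairs"][pair] = {
            c: {k: v for k, v in dataclasses.asdict(t).items()}
            for c, t in ((c, ConditionTruth(**{**_BASE, **kw})) for c, kw in conditions.items())
        }
    table = wells_to_table(all_wells)
    write_plate_csv(table, out / "plate.csv", stimulation_time_s=180.0)

    segments = generate_segment_set(
        n_receptors_per_group=12,
        group_placement={"GRK2/3": "central", "GRK2/3/5/6": "peripheral"},
        seed=seg_seed,
    )
    write_segments_fasta([s.record for s in segments], out / "segments.fasta")
    truth_doc["segments"] = {
        s.record.receptor_id: {
            "group": s.record.group_label,
            "planted": list(map(list, s.planted_motifs)),
        }
        for s in segments
    }

    dmr = generate_dmr_dataset(
        concentrations=(1e-10, 1e-9, 1e-8, 1e-7, 1e-6), truth=DmrTruth(), seed=dmr_seed
    )
    dmr.to_csv(out / "dmr.csv", index=False, float_format="%.10g")
    truth_doc["dmr"] = dataclasses.asdict(DmrTruth())
    _json_dump(truth_doc, out / "truth.json")
    return {"plate": out / "plate.csv", "segments": out / "segments.fasta",
            "dmr": out / "dmr.csv"}


def run_reduce(plate_csv, out_dir, config: RunConfig | None = None) -> Path:
    """Reduce a plate CSV to the tidy per-well fold-change table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or RunConfig()
    table, meta = read_plate_csv(plate_csv)
    wells = plate_to_welltraces(table, meta["stimulation_time_s"])
    reduced = reduce_plate(wells, config)
    reduced.to_csv(out / "reduced.tsv", sep="\t", index=False, float_format="%.10g")
    return out / "reduced.tsv"


def _split_pair(condition: str) -> tuple:
    pair, _, cond = condition.partition(":")
    return (pair, cond) if cond else ("", pair)


def run_fit(reduced_tsv, out_dir, config: RunConfig | None = None) -> Path:
    """Gate every condition and fit concentration-response curves."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or RunConfig()
    reduced = pd.read_csv(reduced_tsv, sep="\t")
    results = {}
    for condition, grp in reduced.groupby("condition", sort=True):
        samples = grp[grp["role"] == "sample"]
        vehicles = grp[grp["role"] == "vehicle"]
        if samples.empty or vehicles.empty:
            continue
        top_c = samples["concentration_M"].max()
        gate = gate_functional_recruitment(
            samples.loc[samples["concentration_M"] == top_c, "fold_change"].to_numpy(),
            vehicles["fold_change"].to_numpy(),
            alpha=config.alpha,
            test=config.gate_test,
        )
        entry = {
            "gate": {"is_functional": gate.is_functional, "p_value": gate.p_value,
                     "test": gate.test_label},
        }
        if gate.is_functional:
            piv = samples.pivot_table(index="replicate", columns="concentration_M",
                                      values="net_fold_change")
            series = ConcentrationSeries(
                concentrations_M=piv.columns.to_numpy(dtype=float),
                responses=piv.to_numpy(dtype=float),
            )
            fit = fit_concentration_response(
                series, gate=gate,
                fix_slope=config.fix_hill_slope,
                per_experiment=config.fit_per_experiment,
            )
            entry["fit"] = {
                "bottom": fit.bottom, "top": fit.top,
                "log_ec50": fit.log_ec50, "log_ec50_sem": fit.log_ec50_sem,
                "hill_slope": fit.hill_slope, "converged": fit.converged,
                "extrapolated": fit.extrapolated, "n_experiments": fit.n_experiments,
            }
        else:
            entry["fit"] = None  # fitting refused: not functional
        results[str(condition)] = entry
    _json_dump(results, out / "fits.json")
    return out / "fits.json"


def run_classify(reduced_tsv, out_dir, config: RunConfig | None = None) -> dict:
    """Selectivity matrix, heatmap, clustering, group calls and pre-coupling."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or RunConfig()
    reduced = pd.read_csv(reduced_tsv, sep="\t")
    reduced = reduced.assign(
        pair=[_split_pair(c)[0] for c in reduced["condition"]],
        cond=[_split_pair(c)[1] for c in reduced["condition"]],
    )
    samples = reduced[reduced["role"] == "sample"]
    top_c = samples.groupby("pair")["concentration_M"].transform("max")
    matrix = (
        samples[samples["concentration_M"] == top_c]
        .rename(columns={"net_fold_change": "value"})[
            ["pair", "cond", "replicate", "value"]
        ]
        .rename(columns={"cond": "condition"})
    )
    res = classify_matrix(
        matrix,
        alpha=config.alpha,
        cap=config.heatmap_cap,
        linkage_method=config.linkage_method,
        pooled_error=config.pooled_error,
    )
    rows = []
    for pair, comps in res["comparisons"].items():
        for c in comps:
            rows.append({
                "pair": pair, "condition_a": c.contrast[0], "condition_b": c.contrast[1],
                "direction": c.direction, "p_unadjusted": c.p_unadjusted,
                "p_adjusted": c.p_adjusted, "method": c.method,
            })
    pd.DataFrame(rows).to_csv(out / "comparisons.tsv", sep="\t", index=False,
                              float_format="%.10g")
    res["heatmap"].to_csv(out / "heatmap.tsv", sep="\t", float_format="%.10g")
    (out / "dendrogram.nwk").write_text(res["newick"] + "\n")

    precoupling = {}
    for pair, grp in reduced.groupby("pair", sort=True):
        sub = grp.copy()
        sub["condition"] = sub["cond"]
        if REFERENCE_CONDITION not in set(sub["condition"]):
            continue
        baselines = per_replicate_baselines(sub, REFERENCE_CONDITION)
        top = sub[(sub["role"] == "sample")
                  & (sub["concentration_M"] == sub["concentration_M"].max())]
        nets = {c: g["net_fold_change"].to_numpy() for c, g in top.groupby("condition")}
        nets[REFERENCE_CONDITION] = top.loc[
            top["condition"] == REFERENCE_CONDITION, "net_fold_change"
        ].to_numpy()
        pc = call_precoupling(baselines, REFERENCE_CONDITION, alpha=config.alpha,
                              net_folds=nets)
        precoupling[pair] = pc
        bars = baseline_bars(sub, REFERENCE_CONDITION)
        bars.to_csv(out / f"baseline_bars_{pair}.tsv", sep="\t", index=False,
                    float_format="%.10g")
    calls = {
        c.pair: {"group": c.group, "leaf_position": c.leaf_position,
                 "precoupling": precoupling.get(c.pair, {}).get("flags", {}),
                 "dampened": precoupling.get(c.pair, {}).get("dampened", {})}
        for c in res["calls"]
    }
    _json_dump(calls, out / "selectivity.json")
    _json_dump(precoupling, out / "precoupling.json")
    return {"calls": calls, "leaf_order": res["leaf_order"]}


def run_motifs(fasta, out_dir, config: RunConfig | None = None) -> dict:
    """Motif scan, positional summaries and Fisher association tests."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or RunConfig()
    segments = [
        s for s in read_segments_fasta(fasta)
        if s.receptor_id not in set(config.exclude_receptors)
    ]
    hits = []
    for seg in segments:
        for motif in ("PPP", "PXPP", "PXPXXP", "PXXPXXP"):
            hits.extend(scan_segment(
                seg, motif,
                overlapping=config.motif_overlapping,
                one_based=config.motif_one_based,
                boundary_central=config.boundary_central,
            ))
    pd.DataFrame([dataclasses.asdict(h) for h in hits]).to_csv(
        out / "motif_hits.tsv", sep="\t", index=False, float_format="%.10g"
    )
    summary = group_summary(hits, segments)
    summary["counts"].to_csv(out / "motif_counts.tsv", sep="\t", index=False,
                             float_format="%.10g")
    summary["class_pies"].to_csv(out / "class_pies.tsv", sep="\t", index=False,
                                 float_format="%.10g")
    assoc = {}
    groups_present = {s.group_label for s in segments}
    if {"GRK2/3", "GRK2/3/5/6"} <= groups_present:
        table = build_contingency(hits, "PXPP", ("GRK2/3", "GRK2/3/5/6"))
        r = fisher_exact(table)
        assoc["PXPP_group"] = {
            "contingency": [list(row) for row in r.contingency],
            "odds_ratio": r.odds_ratio if np.isfinite(r.odds_ratio) else None,
            "p_two_sided": r.p_two_sided,
        }
    classes = {s.receptor_class for s in segments}
    if {"A", "B"} <= classes:
        try:
            table = build_contingency(hits, "PXPP", ("A", "B"), by="receptor_class")
            r = fisher_exact(table)
            assoc["PXPP_class"] = {
                "contingency": [list(row) for row in r.contingency],
                "odds_ratio": r.odds_ratio if np.isfinite(r.odds_ratio) else None,
                "p_two_sided": r.p_two_sided,
            }
        except Exception:
            pass
    _json_dump(assoc, out / "association.json")
    return assoc


def run_dmr(dmr_csv, out_dir, config: RunConfig | None = None) -> dict:
    """Empty-vector-corrected AUC analysis and bottom-constrained fit."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dmr = pd.read_csv(dmr_csv)
    ev = dmr[dmr["role"] == "empty_vector"]
    ev_mean = ev.groupby("time_s")["shift_pm"].mean()
    aucs: dict = {}
    for (c, rep), grp in dmr[dmr["role"] == "sample"].groupby(
        ["concentration_M", "replicate"]
    ):
        grp = grp.sort_values("time_s")
        corrected = grp["shift_pm"].to_numpy() - ev_mean.reindex(grp["time_s"]).to_numpy()
        aucs.setdefault(float(c), []).append(
            dmr_auc(grp["time_s"].to_numpy(), corrected).auc
        )
    top_c = max(aucs)
    reference = float(np.mean(aucs[top_c]))
    effects, fit = dmr_concentration_effect(aucs, reference_auc=reference)
    doc = {
        "reference_auc_pm_s": reference,
        "effects_pct": {f"{c:g}": list(map(float, v)) for c, v in effects.items()},
        "fit": {"bottom": fit.bottom, "top": fit.top, "log_ec50": fit.log_ec50,
                "log_ec50_sem": fit.log_ec50_sem, "converged": fit.converged},
    }
    _json_dump(doc, out / "dmr_fit.json")
    return doc


def run_report(out_dir, seed: int, config: RunConfig | None = None) -> Path:
    """Full chain on the bundled synthetic study; writes one artifact bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or RunConfig(seed=seed)
    paths = run_simulate(out, seed, config)
    run_reduce(paths["plate"], out, config)
    run_fit(out / "reduced.tsv", out, config)
    run_classify(out / "reduced.tsv", out, config)
    run_motifs(paths["segments"], out, config)
    run_dmr(paths["dmr"], out, config)
    log = {
        "package": "grkbret",
        "version": __version__,
        "seed": seed,
        "config": json.loads(config.to_json()),
        "stages": ["simulate", "reduce", "fit", "classify", "motifs", "dmr"],
    }
    _json_dump(log, out / "run_log.json")
    return out / "run_log.json"
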