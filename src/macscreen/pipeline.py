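"""End-to-end orchestration of the coupled phenotype-transcriptome screen.

``run_screen`` ties the stages together on a simulated plate: population
simulation per compound well, flow-cytometry sampling and phenotype
classification (24 hr survival / 72 hr proliferation and differentiation),
pseudo-bulk molecule generation, a full FASTQ write -> demultiplex -> UMI
count round trip, signature AUC scoring, multi-parameter compound selection,
and the standalone integration / CRISPR-screen / ELISpot demonstrations.
All randomness derives from a single config seed via spawned substreams, so
a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import crispr_screen, elispot, integration, macseq_counts, phenotype, signatures
from .synthetic_data import (
    CompoundEffect,
    CytonParams,
    default_gene_model,
    make_layout,
    make_reference,
    sample_flow_events,
    sample_pseudobulk,
    simulate_methylation_rna_tables,
    simulate_population,
    synthesize_crispr_plate,
    synthesize_elispot_stack,
    write_macseq_fastq,
)
from .synthetic_data.flow import DEFAULT_I0

__all__ = ["DEFAULT_CONFIG", "run_screen", "load_config"]

# Default study conditions: single 1 uM dose, 24/72 hr timepoints, 10^4
# calibration beads, 5000-cell transcriptome aliquots represented by a fixed
# sequencing depth per well.
DEFAULT_CONFIG: dict = {
    "seed": 0,
    "times": [24.0, 72.0],
    "dose": 1.0,
    "replicates": 4,
    "beads_added": 10_000,
    "acquisition_fraction": 0.3,
    "ctv_cv": 0.10,
    "depth": 2000,
    "dup_factor": 3,
    "cyton": {},  # overrides for CytonParams fields
    # single-axis archetypes plus the THZ531/SGI-1027-like coupled one
    "compounds": {
        "control": {"s_surv": 1.0, "s_div": 1.0, "s_diff": 1.0},
        "survival-down": {"s_surv": 3.0},
        "survival-up": {"s_surv": 0.2},
        "proliferation-down": {"s_div": 0.85},
        "proliferation-up": {"s_div": 1.15},
        "prc2-inhibitor": {"s_diff": 2.0},
        "differentiation-down": {"s_diff": 0.2},
        "diff-up-death-up": {"s_surv": 3.0, "s_diff": 2.0},
    },
    "gene_model": {"n_genes": 200, "n_asc": 20, "n_apop": 20},
    "alpha": 0.05,
    "stages": {"macseq": True, "integration": True, "crispr": True, "elispot": True},
}


def load_config(path=None) -> dict:
    """Merge a YAML config file over the defaults (shallow per section)."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        import yaml

        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, float_format="%.6g")


def measure_well(
    params: CytonParams,
    effect: CompoundEffect,
    rng: np.random.Generator,
    times=(24.0, 72.0),
    beads_added: int = 10_000,
    ctv_cv: float = 0.10,
    acquisition_fraction: float = 0.3,
) -> dict:
    """Simulate one culture well and measure its phenotype summaries.

    Runs the agent simulation at the two timepoints, samples flow events with
    calibration beads at each, and returns the bead-calibrated 24 hr and
    72 hr absolute counts, the 72 hr mean division number and CD138+
    percentage, plus the two population states (for transcriptome sampling).
    """
    states = simulate_population(params, effect, list(times), rng)
    kwargs = dict(
        beads_added=beads_added,
        ctv_cv=ctv_cv,
        acquisition_fraction=acquisition_fraction,
    )
    ev_first = sample_flow_events(states[0], seed=rng, **kwargs)
    ev_last = sample_flow_events(states[-1], seed=rng, **kwargs)
    c_first = phenotype.build_census(ev_first, i0=DEFAULT_I0, max_gen=params.max_gen)
    c_last = phenotype.build_census(ev_last, i0=DEFAULT_I0, max_gen=params.max_gen)
    return {
        "count_24h": c_first.counts.sum(),
        "count_72h": c_last.counts.sum(),
        "mdn_72h": phenotype.mean_division_number(c_last),
        "cd138_pct_72h": phenotype.differentiation_fraction(c_last),
        "state_24h": states[0],
        "state_72h": states[-1],
    }


def simulate_plate_phenotypes(
    params: CytonParams,
    compounds: dict[str, CompoundEffect],
    replicates: int,
    seed: int,
    times=(24.0, 72.0),
    **measure_kwargs,
) -> pd.DataFrame:
    """Phenotype summary table for a plate of compounds x replicates."""
    rows = []
    streams = np.random.SeedSequence(seed).spawn(len(compounds) * replicates)
    k = 0
    for cid in compounds:
        for rep in range(1, replicates + 1):
            m = measure_well(
                params, compounds[cid], np.random.default_rng(streams[k]),
                times=times, **measure_kwargs,
            )
            rows.append(
                {
                    "compound_id": cid,
                    "replicate": rep,
                    "count_24h": m["count_24h"],
                    "count_72h": m["count_72h"],
                    "mdn_72h": m["mdn_72h"],
                    "cd138_pct_72h": m["cd138_pct_72h"],
                }
            )
            k += 1
    return pd.DataFrame(rows)


def run_screen(config: dict, out_dir) -> dict:
    """Run the full screen described by ``config`` into ``out_dir``.

    Writes per-well phenotype measurements, the per-compound classification,
    the signature score table, the selection table, the stage outputs of the
    integration / CRISPR / ELISpot components, and a ``manifest.json`` with
    the config, seeds and SHA-256 digests of every table.  Returns the
    manifest.  Deterministic given the config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    params = CytonParams(**config.get("cyton", {}))
    compounds = {
        cid: CompoundEffect(compound_id=cid, dose=config["dose"], **eff)
        for cid, eff in config["compounds"].items()
    }
    times = list(config["times"])
    t24, t72 = times[0], times[-1]
    reps = int(config["replicates"])
    gm_cfg = dict(config["gene_model"])
    model = default_gene_model(seed=np.random.default_rng(seed + 1), **gm_cfg)
    layout = make_layout(
        list(compounds), replicates=reps, dose=config["dose"],
        seed=np.random.default_rng(seed + 2),
    )

    # --- simulate + phenotype per well ------------------------------------
    well_rows = []
    counts = {}
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(len(layout.wells))
    for stream, (_, wrow) in zip(streams, layout.wells.iterrows()):
        rng = np.random.default_rng(stream)
        effect = compounds[wrow["compound_id"]]
        m = measure_well(
            params, effect, rng, times=times,
            beads_added=config["beads_added"], ctv_cv=config["ctv_cv"],
            acquisition_fraction=config["acquisition_fraction"],
        )
        well_rows.append(
            {
                "well": wrow["well"],
                "compound_id": wrow["compound_id"],
                "replicate": wrow["replicate"],
                "count_24h": m["count_24h"],
                "count_72h": m["count_72h"],
                "mdn_72h": m["mdn_72h"],
                "cd138_pct_72h": m["cd138_pct_72h"],
            }
        )
        counts[wrow["well"]] = sample_pseudobulk(
            m["state_72h"], model, depth=config["depth"], seed=rng
        )
    wells = pd.DataFrame(well_rows).set_index("well")
    matrix = pd.DataFrame(counts).sort_index()
    classification = phenotype.classify_plate(
        wells.reset_index(), control_id="control", alpha=config["alpha"]
    )

    # --- MAC-seq round trip ------------------------------------------------
    if config["stages"].get("macseq", True):
        reference = make_reference(
            n_genes=len(model.genes), seed=np.random.default_rng(seed + 3)
        )
        ref_named = dict(zip(model.genes, reference.values()))
        molecules = (
            matrix.rename_axis("gene")
            .reset_index()
            .melt(id_vars="gene", var_name="well", value_name="count")
        )
        molecules = molecules[molecules["count"] > 0]
        r1, r2 = out / "reads_R1.fastq.gz", out / "reads_R2.fastq.gz"
        write_macseq_fastq(
            molecules, layout, ref_named, r1, r2,
            dup_factor=config["dup_factor"], error_rate=0.0,
            seed=np.random.default_rng(seed + 4),
        )
        matrix, _stats = macseq_counts.process_fastq_pair(
            r1, r2, layout.barcode_table, ref_named
        )
        matrix = matrix.reindex(
            index=model.genes, columns=layout.wells["well"].sort_values()
        ).fillna(0).astype(int)

    # --- signature scoring + selection ------------------------------------
    norm = macseq_counts.normalize_library_size(matrix)
    gene_sets = {
        "asc_auc": signatures.GeneSet.from_iterable("ASC", sorted(model.asc_set)),
        "apoptotic_auc": signatures.GeneSet.from_iterable(
            "pro-apoptotic", sorted(model.apoptotic_set)
        ),
    }
    aucs = signatures.score_wells(norm, gene_sets)
    score_table = wells.join(aucs)
    score_table = score_table.rename(
        columns={"cd138_pct_72h": "cd138_expression", "count_72h": "cell_number"}
    )
    per_compound = score_table.groupby("compound_id")[
        ["cd138_expression", "cell_number", "asc_auc", "apoptotic_auc"]
    ].mean()
    ctrl_wells = score_table[score_table["compound_id"] == "control"]
    selection_input = pd.concat(
        [per_compound, ctrl_wells[per_compound.columns]]
    )
    selection = signatures.select_multiparameter(
        selection_input, control_wells=ctrl_wells.index
    ).loc[per_compound.index]

    axes = ["survival", "proliferation", "differentiation"]
    report = per_compound.join(classification[axes], how="left").join(
        selection["category"]
    )
    report[axes] = report[axes].fillna("none")  # control has no self-contrast

    _write(wells, out / "wells.csv")
    _write(matrix.rename_axis("gene"), out / "count_matrix.csv")
    _write(score_table, out / "score_table.csv")
    _write(classification, out / "classification.csv")
    _write(report.sort_index(), out / "report.csv")

    # --- standalone stages --------------------------------------------------
    if config["stages"].get("integration", True):
        meth, rna = simulate_methylation_rna_tables(seed=np.random.default_rng(seed + 5))
        bins = integration.bin_methylation_changes(meth)
        _write(
            integration.expression_by_bin(rna, bins), out / "integration_bins.csv"
        )
    if config["stages"].get("crispr", True):
        effects = pd.DataFrame(
            {"effect_untreated": 0.0, "effect_treated": 0.0},
            index=[f"g{i:02d}" for i in range(20)],
        )
        effects.loc["g00", "effect_treated"] = -15.0  # dependence-abolishing
        effects.loc["g01", "effect_untreated"] = 12.0  # PRC2-like boost
        plate = synthesize_crispr_plate(effects, seed=np.random.default_rng(seed + 6))
        _write(plate.set_index("well"), out / "crispr_plate.csv")
        _write(crispr_screen.dependence_zscores(plate), out / "crispr_result.csv")
    if config["stages"].get("elispot", True):
        stack, truth = synthesize_elispot_stack(
            n_spots=[0, 2, 4, 6, 8, 10, 12, 14, 16, 18, 20, 22],
            seed=np.random.default_rng(seed + 7),
        )
        table, _results = elispot.analyze_stack(stack)
        table["true_n_spots"] = truth["n_spots"]
        _write(table.set_index("well_index"), out / "elispot_counts.csv")

    manifest = {
        "config": config,
        "outputs": {
            p.name: _sha256(p) for p in sorted(out.glob("*.csv"))
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
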