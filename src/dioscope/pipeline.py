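"""End-to-end orchestration: features → AE → DIO → clusters → roles.

One *combination* pairs an apo feature set (which trains its own
autoencoder) with a holo feature set inspected by that model; a
replicated study design (apo1/apo2 × holo1/holo2) is a list of such
combinations whose role tables are aggregated with provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .autoencoder import AEConfig, reconstruct, train_ae
from .dio_cluster import compute_dio, cosine_distance_matrix, stack_dio, ward_d2_cluster
from .md_features import FeatureMatrix, build_feature_matrix, load_trajectory
from .regions import RegionMap, load_helix_table, build_region_map
from .roles_eval import (
    ACCM_THRESHOLD,
    LEAD_THRESHOLD,
    aggregate_combinations,
    evaluate_against_reference,
    extract_roles,
)

__all__ = ["RunConfig", "CombinationResult", "PipelineResult", "analyze_combination", "run_pipeline", "run_synthetic"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """File-based pipeline configuration (see the CLI ``run`` subcommand)."""

    apo_inputs: dict[str, dict]  # id -> {"topology": ..., "trajectory": ...}
    holo_inputs: dict[str, dict]
    window: tuple[float, float, float]
    ae: dict = field(default_factory=dict)  # AEConfig overrides (input_dim inferred)
    k_range: tuple[int, int] = (2, 9)
    lead_threshold: float = LEAD_THRESHOLD
    accm_threshold: float = ACCM_THRESHOLD
    helix_table: str | None = None
    flank: int = 8
    reference: str | None = None  # TSV with a "residue" column
    mapping: str | None = None  # two-column TSV: reference residue -> model residue
    ligand_chains: tuple[str, ...] = ("L",)
    seed: int = 0
    out_dir: str = "dioscope_out"

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class CombinationResult:
    combination: str
    model: object
    train_report: object
    dio_apo: object
    dio_holo: object
    dendrogram: object
    role_table: pd.DataFrame
    chosen_k: int
    exhausted: bool
    tables_by_k: dict[int, pd.DataFrame]


@dataclass
class PipelineResult:
    combinations: dict[str, CombinationResult]
    aggregate: pd.DataFrame
    evaluation: object | None
    report: dict


def analyze_combination(
    apo_features: FeatureMatrix,
    holo_features: FeatureMatrix,
    ae_config: AEConfig,
    k_range: tuple[int, int] = (2, 9),
    lead_threshold: float = LEAD_THRESHOLD,
    accm_threshold: float = ACCM_THRESHOLD,
    region_map: RegionMap | None = None,
    combination: str = "apo-holo",
    receptor_residues: set[int] | None = None,
) -> CombinationResult:
    """Run one apo–holo combination through the DIO pipeline.

    Trains the autoencoder on the apo features, inspects both sets,
    clusters the joint DIO rows (cosine + Ward.D2), scans tree cuts with
    the stopping rule, and extracts Lead/Accm roles.
    """
    model, report = train_ae(apo_features, ae_config)
    dio_apo = compute_dio(apo_features, reconstruct(model, apo_features), source="apo")
    dio_holo = compute_dio(holo_features, reconstruct(model, holo_features), source="holo")

    rows, leaves = stack_dio(dio_apo, dio_holo)
    D = cosine_distance_matrix(rows)
    dendrogram = ward_d2_cluster(D, leaves=leaves)

    universe = {r for pair in holo_features.pairs for r in pair}
    universe |= {r for pair in apo_features.pairs for r in pair}
    role_table, chosen_k, exhausted, tables_by_k = extract_roles(
        dendrogram,
        universe,
        k_range=k_range,
        receptor_residues=receptor_residues,
        lead_threshold=lead_threshold,
        accm_threshold=accm_threshold,
        region_map=region_map,
        combination=combination,
    )
    logger.info(
        "%s: %d apo + %d holo pairs, chosen k=%d%s, %d role rows",
        combination,
        dio_apo.n_pairs,
        dio_holo.n_pairs,
        chosen_k,
        " (exhausted)" if exhausted else "",
        len(role_table),
    )
    return CombinationResult(
        combination=combination,
        model=model,
        train_report=report,
        dio_apo=dio_apo,
        dio_holo=dio_holo,
        dendrogram=dendrogram,
        role_table=role_table,
        chosen_k=chosen_k,
        exhausted=exhausted,
        tables_by_k=tables_by_k,
    )


def run_synthetic(
    synth_config,
    ae_config: AEConfig | None = None,
    k_range: tuple[int, int] = (2, 9),
    sample_stride: int = 10,
) -> tuple[CombinationResult, set[int]]:
    """Generate an apo/holo fixture pair and run one combination in memory.

    The feature window spans the whole trajectory sampled every
    ``sample_stride`` frames; the autoencoder defaults to the desk-scale
    profile seeded from the generator seed.  Returns the combination
    result together with the planted signaling residue set.
    """
    from .md_features import build_feature_matrix
    from .synthetic_data import generate_apo, generate_holo

    apo = generate_apo(synth_config)
    holo, truth = generate_holo(synth_config)
    window = (0.0, float(apo.times[-1]), synth_config.frame_interval * sample_stride)
    apo_features = build_feature_matrix(apo, window=window)
    holo_features = build_feature_matrix(holo, window=window)
    if ae_config is None:
        ae_config = AEConfig.desk_scale(apo_features.n_steps, seed=synth_config.seed)
    result = analyze_combination(
        apo_features, holo_features, ae_config, k_range=k_range, combination="apo-holo"
    )
    return result, truth


def _load_reference(path: str) -> set[int]:
    df = pd.read_csv(path, sep="\t")
    col = "residue" if "residue" in df.columns else df.columns[0]
    return set(df[col].astype(int).tolist())


def _load_mapping(path: str) -> dict[int, int]:
    df = pd.read_csv(path, sep="\t")
    a, b = df.columns[:2]
    return dict(zip(df[a].astype(int), df[b].astype(int)))


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute extract → train → inspect → DIO → cluster → roles → evaluate.

    Each apo replicate trains its own autoencoder; every apo × holo
    combination is clustered separately and the role tables are
    aggregated.  Outputs (role TSVs, aggregate, report JSON) are written
    under ``config.out_dir`` tagged with the config hash; identical
    config and seeds reproduce identical files.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    region_map = None
    if config.helix_table:
        region_map = build_region_map(load_helix_table(config.helix_table), config.flank)

    def stage(name: str, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    def extract(spec: dict) -> FeatureMatrix:
        frames = load_trajectory(
            spec["topology"],
            spec.get("trajectory"),
            ligand_chains=frozenset(config.ligand_chains),
            dt_ns=spec.get("dt_ns"),
        )
        return build_feature_matrix(frames, window=config.window)

    apo_features = {aid: stage(f"extract:{aid}", lambda s=s: extract(s)) for aid, s in config.apo_inputs.items()}
    holo_features = {hid: stage(f"extract:{hid}", lambda s=s: extract(s)) for hid, s in config.holo_inputs.items()}

    combos: dict[str, CombinationResult] = {}
    for aid, af in apo_features.items():
        ae_kwargs = dict(config.ae)
        ae_kwargs.setdefault("input_dim", af.n_steps)
        ae_kwargs.setdefault("seed", config.seed)
        ae_config = AEConfig(**ae_kwargs)
        receptor = {
            r
            for pair, mols in zip(af.pairs, af.pair_molecules)
            for r, m in zip(pair, mols)
            if m == "receptor"
        } or None
        for hid, hf in holo_features.items():
            name = f"{aid}-{hid}"
            combos[name] = stage(
                name,
                lambda af=af, hf=hf, name=name, ae_config=ae_config, receptor=receptor: analyze_combination(
                    af,
                    hf,
                    ae_config,
                    k_range=config.k_range,
                    lead_threshold=config.lead_threshold,
                    accm_threshold=config.accm_threshold,
                    region_map=region_map,
                    combination=name,
                    receptor_residues=receptor,
                ),
            )
            combos[name].role_table.to_csv(out / f"roles_{name}_{chash}.tsv", sep="\t", index=False)

    aggregate = aggregate_combinations(
        {name: c.role_table for name, c in combos.items()}, region_map=region_map
    )
    aggregate.to_csv(out / f"roles_aggregate_{chash}.tsv", sep="\t", index=False)

    evaluation = None
    if config.reference:
        detected = set(aggregate["residue"].tolist())
        reference = _load_reference(config.reference)
        mapping = _load_mapping(config.mapping) if config.mapping else None
        evaluation = evaluate_against_reference(detected, reference, mapping)

    report = {
        "config_hash": chash,
        "seed": config.seed,
        "n_pairs": {k: f.n_pairs for k, f in {**apo_features, **holo_features}.items()},
        "n_steps": {k: f.n_steps for k, f in {**apo_features, **holo_features}.items()},
        "chosen_k": {name: c.chosen_k for name, c in combos.items()},
        "n_role_rows": {name: int(len(c.role_table)) for name, c in combos.items()},
        "n_aggregate_residues": int(len(aggregate)),
        "dio_sign": "input_minus_output",
    }
    if evaluation is not None:
        report["evaluation"] = {
            "recall": evaluation.recall,
            "precision": evaluation.precision,
            "overlap": sorted(evaluation.overlap),
        }
    (out / f"report_{chash}.json").write_text(json.dumps(report, indent=2, default=str))
    return PipelineResult(combinations=combos, aggregate=aggregate, evaluation=evaluation, report=report)
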