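"""End-to-end screen orchestration: signature -> rank -> network -> synergy.

A single YAML/JSON config drives the run.  Each stage can read real input
files or consume the synthetic generators; stage outputs are written to the
output directory as TSV/JSON so any downstream stage can be resumed from disk.
Reports carry a provenance block (tool version, seed, config hash, input file
digests) and contain no timestamps, so identical config + seed reproduces a
byte-identical report.

Default thresholds mirror the screen's standard operating point: |log2FC| > 1,
FDR < 0.1, reference min_fraction 0.5, correlation cut 0.7, 100 permutations,
top_k 3, tissue TPM > 1, 3x3 synergy window.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as cio
from .network import ProteinSet, classify_exposure, tissue_filter
from .orthogonality import rank_candidates
from .signatures import (
    compute_disease_signature,
    compute_reference_signature,
)
from .simulate import (
    CohortConfig,
    DoseConfig,
    NetworkConfig,
    PanelConfig,
    gen_cohort,
    gen_dose_matrix,
    gen_perturbation_panel,
    gen_ppi_with_modules,
)
from .synergy import bliss_delta, zip_delta

__all__ = ["ScreenReport", "run_screen", "validate_inputs", "load_config"]

log = logging.getLogger("combiscreen")

DEFAULTS = {
    "seed": 0,
    "output_dir": "screen_out",
    "signature": {"enabled": True, "lfc_threshold": 1.0, "fdr_threshold": 0.1},
    "rank": {
        "enabled": True,
        "top_k": 3,
        "min_fraction": 0.5,
        "mode": "normalized",
        "reference": None,
        "reference_cell_lines": None,
    },
    "network": {
        "enabled": True,
        "n_permutations": 100,
        "tissue_tpm": None,
        "scenarios": ["complementary", "overlapping", "single"],
    },
    "synergy": {"enabled": True, "models": ["bliss", "zip"], "planted_delta": 0.10},
    "simulate": {"enabled": True},
    "inputs": {},
}


@dataclass
class ScreenReport:
    """Assembled screen results plus provenance."""

    ranking: dict = field(default_factory=dict)
    exposure: list = field(default_factory=list)
    synergy: list = field(default_factory=list)
    stages: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def _deep_update(base: dict, overrides: dict) -> dict:
    out = dict(base)
    for k, v in overrides.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None) -> dict:
    overrides = {}
    if path is not None:
        with open(path) as fh:
            overrides = yaml.safe_load(fh) or {}
    return _deep_update(DEFAULTS, overrides)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def validate_inputs(config_path: str | Path | None) -> dict:
    """Check input files and cross-stage consistency without modifying data.

    Returns {"errors": [...], "warnings": [...], "checks": {...}}.  Unreadable
    files are listed as errors (non-fatal here; ``run_screen`` enforces them).
    """
    config = load_config(config_path)
    errors: list[str] = []
    warns: list[str] = []
    checks: dict = {}
    inputs = config.get("inputs") or {}
    loaded: dict = {}
    readers = {
        "expression": lambda p: cio.read_expression_tsv(p, inputs["conditions"]),
        "panel": cio.read_panel_tsv,
        "edges": cio.read_edge_list,
        "protein_sets": cio.read_protein_sets,
        "dose_matrix": cio.read_dose_matrix_csv,
    }
    for key, reader in readers.items():
        path = inputs.get(key)
        if path is None:
            continue
        try:
            with warnings_to(warns):
                loaded[key] = reader(path)
            checks[key] = "ok"
        except Exception as exc:  # noqa: BLE001 - report, don't crash
            errors.append(f"{key}: {path}: {exc}")
            checks[key] = "error"
    if "expression" in loaded and "panel" in loaded:
        cohort_genes = set(loaded["expression"].genes)
        panel_genes = set(loaded["panel"].genes)
        shared = cohort_genes & panel_genes
        if not shared:
            errors.append("cohort and panel gene universes are disjoint")
        elif len(shared) < 0.5 * min(len(cohort_genes), len(panel_genes)):
            warns.append(
                f"only {len(shared)} genes shared between cohort "
                f"({len(cohort_genes)}) and panel ({len(panel_genes)})"
            )
        checks["gene_overlap"] = len(shared)
    if "edges" in loaded and "protein_sets" in loaded:
        nodes = set(loaded["edges"].nodes())
        for label, pset in loaded["protein_sets"].items():
            inter = len(pset.members & nodes)
            checks[f"set_{label}_in_graph"] = inter
            if inter == 0:
                errors.append(f"protein set {label!r} does not intersect the graph")
    return {"errors": errors, "warnings": warns, "checks": checks}


class warnings_to:
    """Context manager collecting warning messages into a list."""

    def __init__(self, sink: list):
        self.sink = sink

    def __enter__(self):
        import warnings as _w

        self._cm = _w.catch_warnings(record=True)
        self._records = self._cm.__enter__()
        import warnings as _w2

        _w2.simplefilter("always")
        return self

    def __exit__(self, *exc):
        self._cm.__exit__(*exc)
        self.sink.extend(str(r.message) for r in self._records)
        return False


def run_screen(config_path: str | Path | None = None, config: dict | None = None) -> ScreenReport:
    """Execute the enabled stages in order and write the report.

    In simulate mode every stage's input comes from the seeded generators; the
    network stage evaluates one planted graph scenario per top-ranked pair
    (the last pair deliberately lacks curated targets and is reported as
    "not assessable"), and the synergy stage scores one generated checkerboard
    per pair with the configured planted delta.
    """
    if config is None:
        config = load_config(config_path)
    else:
        config = _deep_update(DEFAULTS, config)
    stages_enabled = [
        s for s in ("signature", "rank", "network", "synergy") if config[s]["enabled"]
    ]
    if not stages_enabled:
        raise ValueError("all stages disabled; nothing to run")
    if not config["signature"]["enabled"]:
        raise ValueError("the transcriptomics (signature) stage must be enabled")
    out_dir = Path(config["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(8)]
    report = ScreenReport()
    report.provenance = {
        "tool": "combiscreen",
        "version": __version__,
        "seed": seed,
        "config_hash": _config_hash(config),
        "input_digests": {
            k: _file_digest(v)
            for k, v in (config.get("inputs") or {}).items()
            if v and Path(str(v)).is_file()
        },
    }
    simulate = bool(config["simulate"]["enabled"])
    inputs = config.get("inputs") or {}

    # -- stage 1: disease signature ------------------------------------
    if simulate:
        cohort, cohort_truth = gen_cohort(CohortConfig(), seed=seeds[0])
        cohort_truth.to_csv(out_dir / "cohort_truth.tsv", sep="\t")
    else:
        cohort = cio.read_expression_tsv(inputs["expression"], inputs["conditions"])
    sig_cfg = config["signature"]
    disease = compute_disease_signature(
        cohort, sig_cfg["lfc_threshold"], sig_cfg["fdr_threshold"]
    )
    cio.write_signature_tsv(disease, out_dir / "disease_signature.tsv")
    report.stages["signature"] = {
        "status": "ok",
        "n_up": disease.n_up,
        "n_down": disease.n_down,
    }
    log.info("signature: %d up, %d down", disease.n_up, disease.n_down)

    # -- stage 2: orthogonality ranking --------------------------------
    top_pairs: list[str] = []
    reference_id = config["rank"].get("reference")
    if config["rank"]["enabled"]:
        rank_cfg = config["rank"]
        if simulate:
            panel_cfg = PanelConfig()
            panel, panel_truth = gen_perturbation_panel(
                panel_cfg, disease, seed=seeds[1]
            )
            reference_id = reference_id or panel_truth["reference_id"]
            call_threshold = rank_cfg.get("call_threshold", panel_cfg.call_threshold)
        else:
            panel = cio.read_panel_tsv(inputs["panel"])
            if reference_id is None:
                raise ValueError("rank.reference must name the reference compound")
            call_threshold = rank_cfg.get("call_threshold", 0.0)
        ref_sig = compute_reference_signature(
            panel,
            reference_id,
            cell_line_filter=rank_cfg.get("reference_cell_lines"),
            min_fraction=rank_cfg["min_fraction"],
            per_experiment_threshold=call_threshold,
        )
        ranking = rank_candidates(
            panel,
            reference_id,
            disease,
            top_k=rank_cfg["top_k"],
            reference_signature=ref_sig,
            mode=rank_cfg["mode"],
            per_experiment_threshold=call_threshold,
        )
        ranking.table.to_csv(out_dir / f"ranking_{reference_id}.tsv", sep="\t", index=False)
        top_pairs = ranking.top_compounds
        report.ranking = {
            "reference": reference_id,
            "top": top_pairs,
            "n_valid": len(ranking.table),
            "n_flagged": len(ranking.flagged),
        }
        report.stages["rank"] = {"status": "ok"}
        log.info("rank: top-%d = %s", rank_cfg["top_k"], top_pairs)
    else:
        report.stages["rank"] = {"status": "skipped", "reason": "disabled"}

    # -- stage 3: network assessment -----------------------------------
    if config["network"]["enabled"]:
        net_cfg = config["network"]
        if simulate and top_pairs:
            scenarios = list(net_cfg["scenarios"])
            rng = np.random.default_rng(seeds[2])
            for i, candidate in enumerate(top_pairs):
                if i >= len(scenarios):
                    # mirrors a candidate with no curated target proteins
                    report.exposure.append(
                        {
                            "pair": [reference_id, candidate],
                            "status": "not assessable",
                            "reason": "no curated target proteins",
                        }
                    )
                    continue
                scenario = scenarios[i]
                graph, dis, drug_a, drug_b, planted = gen_ppi_with_modules(
                    NetworkConfig(), scenario=scenario, seed=int(rng.integers(2**31))
                )
                call = classify_exposure(
                    graph,
                    dis,
                    drug_a,
                    drug_b,
                    n_permutations=net_cfg["n_permutations"],
                    seed=int(rng.integers(2**31)),
                )
                report.exposure.append(
                    {
                        "pair": [reference_id, candidate],
                        "status": "ok",
                        "z_a": call.z_a,
                        "z_b": call.z_b,
                        "s_ab": call.s_ab,
                        "category": call.category,
                        "planted_category": planted,
                    }
                )
            report.stages["network"] = {"status": "ok"}
        elif not simulate and {"edges", "protein_sets"} <= set(inputs):
            graph = cio.read_edge_list(inputs["edges"])
            if net_cfg.get("tissue_tpm") is not None and "node_expression" in inputs:
                expr = cio.read_node_expression(inputs["node_expression"])
                graph = tissue_filter(graph, expr, net_cfg["tissue_tpm"])
            sets = cio.read_protein_sets(inputs["protein_sets"])
            disease_set = sets.get("disease")
            if disease_set is None:
                raise ValueError("protein sets must include a 'disease' label")
            drug_labels = sorted(k for k in sets if k != "disease")
            rng = np.random.default_rng(seeds[2])
            for i, la in enumerate(drug_labels):
                for lb in drug_labels[i + 1 :]:
                    if len(sets[la]) == 0 or len(sets[lb]) == 0:
                        report.exposure.append(
                            {
                                "pair": [la, lb],
                                "status": "not assessable",
                                "reason": "no curated target proteins",
                            }
                        )
                        continue
                    call = classify_exposure(
                        graph,
                        disease_set,
                        sets[la],
                        sets[lb],
                        n_permutations=net_cfg["n_permutations"],
                        seed=int(rng.integers(2**31)),
                    )
                    report.exposure.append(
                        {
                            "pair": [la, lb],
                            "status": "ok",
                            "z_a": call.z_a,
                            "z_b": call.z_b,
                            "s_ab": call.s_ab,
                            "category": call.category,
                        }
                    )
            report.stages["network"] = {"status": "ok"}
        else:
            report.stages["network"] = {
                "status": "skipped",
                "reason": "no graph/target inputs",
            }
    else:
        report.stages["network"] = {"status": "skipped", "reason": "disabled"}

    # -- stage 4: synergy scoring --------------------------------------
    if config["synergy"]["enabled"]:
        syn_cfg = config["synergy"]
        matrices: list[tuple[str, object, object]] = []
        if simulate and top_pairs:
            rng = np.random.default_rng(seeds[3])
            for candidate in top_pairs:
                dose_cfg = DoseConfig(planted_delta=syn_cfg["planted_delta"])
                matrix, truth = gen_dose_matrix(
                    dose_cfg,
                    drug_a=str(reference_id),
                    drug_b=str(candidate),
                    seed=int(rng.integers(2**31)),
                )
                matrices.append((f"{reference_id}-{candidate}", matrix, truth))
        elif not simulate and "dose_matrix" in inputs:
            matrix = cio.read_dose_matrix_csv(inputs["dose_matrix"])
            matrices.append((f"{matrix.drug_a}-{matrix.drug_b}", matrix, None))
        for pair, matrix, truth in matrices:
            entry: dict = {"pair": pair}
            for model in syn_cfg["models"]:
                result = bliss_delta(matrix) if model == "bliss" else zip_delta(matrix)
                entry[model] = {
                    "synergy_score": result.synergy_score,
                    "most_synergistic_area": result.most_synergistic_area,
                }
                np.savetxt(
                    out_dir / f"delta_{model}_{pair}.tsv",
                    result.delta,
                    delimiter="\t",
                    fmt="%.6g",
                )
            if truth is not None:
                entry["planted_delta_pp"] = float(np.mean(truth)) * 100.0
            report.synergy.append(entry)
        report.stages["synergy"] = {
            "status": "ok" if matrices else "skipped",
            **({} if matrices else {"reason": "no dose matrices"}),
        }
    else:
        report.stages["synergy"] = {"status": "skipped", "reason": "disabled"}

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
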