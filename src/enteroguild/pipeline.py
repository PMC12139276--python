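"""Config-driven orchestration: simulate -> preprocess -> rank -> fit ->
characterize -> assoc -> h2.

Each stage reads its inputs from the previous stage's output files,
writes its results plus a JSON provenance block (parameter values, seed,
SHA-256 checksums of the input files), and is skipped on rerun when an
existing provenance block matches — a checksum change anywhere upstream
recomputes everything downstream.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, characterize, genetics, io, preprocess, rank, synthetic
from .nmf import fit_nmf
from .types import ESDecomposition

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

logger = logging.getLogger("enteroguild")

STAGES = ("simulate", "preprocess", "rank", "fit", "characterize", "assoc", "h2")

DEFAULTS: dict = {
    "simulate": {
        "n_genera": 80,
        "k_true": 5,
        "driver_weight": 0.5,
        "sparsity": 0.5,
        "n_samples": 400,
        "depth_log_mean": float(np.log(20_000)),
        "depth_log_sd": 0.35,
        "n_snp": 2000,
        "maf_low": 0.05,
        "maf_high": 0.5,
        "missing_rate": 0.03,
        "h2": 0.30,
        "n_causal": 100,
        # (guild index, trait, slope); cortisol negatively coupled to guild 0
        "trait_effects": [[0, "cortisol", -1.0], [1, "ADG", 0.8]],
        "trait_noise_sd": 0.1,
        "stress_shift": None,
    },
    "preprocess": {
        "min_sample_presence": 2,
        "min_total_fraction": 1e-6,
        "min_depth": 10_000,
        "min_prevalence": 0.20,
    },
    "rank": {
        "k_min": 2,
        "k_max": 8,
        "n_repetitions": 20,
        "n_restarts": 5,
        "max_iter": 200,
        "tol": 1e-4,
        "plateau_tol": 0.01,
        "metric": "cosine_total",
    },
    "fit": {"k": None, "n_restarts": 20, "max_iter": 2000, "tol": 1e-6},
    "characterize": {"coverage": 0.90, "group": "batch", "threshold": 0.04},
    "assoc": {"traits": ["cortisol", "ADG"], "group": "group"},
    "h2": {
        "n_iter": 20_000,
        "burn_in": 500,
        "thin": 5,
        "prior_df": 5.0,
        "factors": ["batch", "sex"],
        "covariates": ["age"],
        "maf_min": 0.05,
        "missing_max": 0.10,
    },
}


class RunConfig:
    """Validated pipeline configuration (YAML file or plain dict)."""

    def __init__(self, data: dict):
        if not isinstance(data, dict):
            raise ValueError("config: expected a mapping at the top level")
        unknown = set(data) - set(STAGES) - {"seed", "out_dir", "stages"}
        if unknown:
            raise ValueError(f"config: unknown top-level keys {sorted(unknown)}")
        self.seed = int(data.get("seed", 0))
        if "out_dir" not in data:
            raise ValueError("config: 'out_dir' is required")
        self.out_dir = Path(data["out_dir"])
        self.stages = list(data.get("stages", STAGES))
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ValueError(f"config: stages: unknown stage(s) {bad}")
        self.params: dict = {}
        for stage in STAGES:
            block = dict(DEFAULTS[stage])
            override = data.get(stage) or {}
            unknown = set(override) - set(block)
            if unknown:
                raise ValueError(f"config: {stage}: unknown key(s) {sorted(unknown)}")
            block.update(override)
            self.params[stage] = block

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _provenance(stage_dir: Path, params: dict, seed: int, inputs: list) -> dict:
    return {
        "params": json.loads(json.dumps(params, default=str)),
        "seed": seed,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs},
    }


def _stage_cached(stage_dir: Path, prov: dict) -> bool:
    pfile = stage_dir / "provenance.json"
    if not pfile.exists():
        return False
    try:
        old = json.loads(pfile.read_text())
    except json.JSONDecodeError:
        return False
    if old.get("params") != prov["params"] or old.get("seed") != prov["seed"]:
        return False
    if old.get("inputs") != prov["inputs"]:
        return False
    return all(Path(f).exists() for f in old.get("outputs", []))


def _finish_stage(stage_dir: Path, prov: dict, outputs: list) -> None:
    prov["outputs"] = [str(p) for p in outputs]
    io.write_json(prov, stage_dir / "provenance.json")


def run_pipeline(config: RunConfig) -> dict:
    """Execute enabled stages in order; returns the run manifest."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}
    t_all = time.time()
    for stage in STAGES:
        if stage not in config.stages:
            continue
        stage_dir = out / stage
        stage_dir.mkdir(exist_ok=True)
        runner = _RUNNERS[stage]
        inputs = runner.inputs(out)
        missing = [p for p in inputs if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"stage {stage}: missing inputs {missing}")
        prov = _provenance(stage_dir, config.params[stage], config.seed, inputs)
        t0 = time.time()
        if _stage_cached(stage_dir, prov):
            status = "cached"
            outputs = json.loads((stage_dir / "provenance.json").read_text())["outputs"]
        else:
            try:
                outputs = runner.run(out, stage_dir, config.params[stage], config.seed)
            except Exception:
                logger.exception("stage %s failed", stage)
                raise
            _finish_stage(stage_dir, prov, outputs)
            status = "completed"
        logger.info("stage %s: %s (%.1fs)", stage, status, time.time() - t0)
        manifest["stages"][stage] = {
            "status": status,
            "outputs": {str(f): _sha256(Path(f)) for f in outputs},
            "wall_time_s": round(time.time() - t0, 3),
        }
    manifest["total_wall_time_s"] = round(time.time() - t_all, 3)
    io.write_json(manifest, out / "manifest.json")
    return manifest


class _Stage:
    def __init__(self, inputs_fn, run_fn):
        self.inputs = inputs_fn
        self.run = run_fn


def _run_simulate(out: Path, d: Path, p: dict, seed: int) -> list:
    truth = synthetic.simulate_guilds(
        p["n_genera"], p["k_true"], p["driver_weight"], p["sparsity"], seed
    )
    stress_shift = None
    if p["stress_shift"]:
        stress_shift = {
            truth.guild_names[int(i)]: float(v) for i, v in dict(p["stress_shift"]).items()
        }
    table, struth = synthetic.simulate_samples(
        truth,
        p["n_samples"],
        depth_log_mean=p["depth_log_mean"],
        depth_log_sd=p["depth_log_sd"],
        seed=seed + 1,
        stress_shift=stress_shift,
    )
    effects = [(truth.guild_names[int(i)], t, float(s)) for i, t, s in p["trait_effects"]]
    traits = synthetic.simulate_traits(struth, effects, p["trait_noise_sd"], seed=seed + 2)
    meta = struth.group_labels.merge(traits, on="sample_id")

    geno = synthetic.simulate_genotypes(
        p["n_samples"], p["n_snp"], p["maf_low"], p["maf_high"], p["missing_rate"], seed + 3
    )
    y_sim, gtruth = synthetic.simulate_heritable_es(
        geno, p["h2"], p["n_causal"], fixed_design=meta[["batch", "sex", "age"]], seed=seed + 4
    )
    meta["es_sim"] = y_sim  # a directly heritable synthetic signature abundance

    io.write_count_table(table, d / "counts.tsv")
    meta.to_csv(d / "metadata.tsv", sep="\t", index=False)
    io.write_genotypes_tsv(geno, d / "genotypes.tsv")
    io.write_json(
        {
            "W_true": truth.W_true,
            "driver_ids": truth.driver_ids,
            "genus_ids": truth.genus_ids,
            "k_true": truth.k_true,
            "H_true": struth.H_true,
            "h2_true": gtruth.h2_true,
            "u_true": gtruth.u_true,
        },
        d / "truth.json",
    )
    return [d / "counts.tsv", d / "metadata.tsv", d / "genotypes.tsv", d / "truth.json"]


def _run_preprocess(out: Path, d: Path, p: dict, seed: int) -> list:
    table = io.read_count_table(out / "simulate" / "counts.tsv")
    table.taxonomy = {f: f for f in table.feature_ids}  # already genus-level
    X, report = preprocess.make_nmf_input(
        table,
        min_sample_presence=p["min_sample_presence"],
        min_total_fraction=p["min_total_fraction"],
        min_depth=p["min_depth"],
        min_prevalence=p["min_prevalence"],
    )
    io.write_matrix_tsv(X, d / "relabund.tsv", index_label="genus_id")
    io.write_json(report, d / "qc_report.json")
    return [d / "relabund.tsv", d / "qc_report.json"]


def _run_rank(out: Path, d: Path, p: dict, seed: int) -> list:
    df = io.read_matrix_tsv(out / "preprocess" / "relabund.tsv")
    X = df.to_numpy()
    result = rank.bicv_curve(
        X,
        k_range=range(p["k_min"], p["k_max"] + 1),
        n_repetitions=p["n_repetitions"],
        nmf_params={"n_restarts": p["n_restarts"], "max_iter": p["max_iter"], "tol": p["tol"]},
        seed=seed,
    )
    k_sel = rank.select_rank(result, metric=p["metric"], plateau_tol=p["plateau_tol"])
    result.to_frame().to_csv(d / "bicv_long.tsv", sep="\t", index=False)
    io.write_json(
        {
            "selected_k": k_sel,
            "metric": p["metric"],
            "plateau_tol": p["plateau_tol"],
            "medians": {
                str(k): float(np.median(result.per_k[k][p["metric"]])) for k in result.k_values
            },
        },
        d / "rank.json",
    )
    return [d / "bicv_long.tsv", d / "rank.json"]


def _run_fit(out: Path, d: Path, p: dict, seed: int) -> list:
    df = io.read_matrix_tsv(out / "preprocess" / "relabund.tsv")
    k = p["k"] or io.read_json(out / "rank" / "rank.json")["selected_k"]
    dec = fit_nmf(
        df.to_numpy(),
        k=int(k),
        n_restarts=p["n_restarts"],
        max_iter=p["max_iter"],
        tol=p["tol"],
        seed=seed,
    )
    prof = characterize.make_profile(
        ESDecomposition(
            W=dec.W, H=dec.H, k=dec.k, loss=dec.loss, n_iter=dec.n_iter, seed=dec.seed,
            genus_ids=list(df.index), sample_ids=list(df.columns), metrics=dec.metrics,
        )
    )
    pd.DataFrame(dec.W, index=df.index, columns=prof.es_names).to_csv(
        d / "W.tsv", sep="\t", index_label="genus_id"
    )
    pd.DataFrame(dec.H, index=prof.es_names, columns=df.columns).to_csv(
        d / "H.tsv", sep="\t", index_label="es"
    )
    io.write_json(
        {
            "k": dec.k,
            "loss": dec.loss,
            "n_iter": dec.n_iter,
            "best_restart_seed": dec.seed,
            "metrics": {
                m: dec.metrics[m]
                for m in (
                    "explained_variance",
                    "reconstruction_error",
                    "cosine_similarity_mean",
                    "cosine_similarity_median",
                    "cosine_similarity_total",
                )
            },
        },
        d / "fit_report.json",
    )
    return [d / "W.tsv", d / "H.tsv", d / "fit_report.json"]


def _load_fractions(out: Path):
    from .types import SampleESFractions

    H = io.read_matrix_tsv(out / "fit" / "H.tsv")
    fr = H.to_numpy()
    fr = fr / fr.sum(axis=0)
    return SampleESFractions(
        fractions=fr, sample_ids=list(map(str, H.columns)), es_names=list(H.index)
    )


def _run_characterize(out: Path, d: Path, p: dict, seed: int) -> list:
    W = io.read_matrix_tsv(out / "fit" / "W.tsv")
    meta = io.read_metadata(out / "simulate" / "metadata.tsv")
    rep = io.read_json(out / "fit" / "fit_report.json")
    dec = ESDecomposition(
        W=W.to_numpy(),
        H=_load_fractions(out).fractions,
        k=int(rep["k"]),
        loss=float(rep["loss"]),
        n_iter=int(rep["n_iter"]),
        seed=int(rep["best_restart_seed"]),
        genus_ids=list(W.index),
        sample_ids=_load_fractions(out).sample_ids,
    )
    prof = characterize.make_profile(dec)
    fracs = characterize.sample_fractions(dec, es_names=prof.es_names)
    prof.contributions_frame().to_csv(d / "contributions.tsv", sep="\t", index_label="genus_id")
    prof.assignment_frame().to_csv(d / "assignment_prob.tsv", sep="\t", index_label="genus_id")
    fracs.to_frame().to_csv(d / "fractions.tsv", sep="\t", index_label="es")
    characterize.top_contributors(prof, p["threshold"]).to_csv(
        d / "top_contributors.tsv", sep="\t", index_label="genus_id"
    )
    meta_idx = meta.set_index("sample_id").loc[fracs.sample_ids]
    summary = characterize.minimal_es_set(
        fracs, meta_idx[p["group"]].to_numpy(), coverage=p["coverage"]
    )
    io.write_json(summary, d / "group_summary.json")
    return [
        d / "contributions.tsv",
        d / "assignment_prob.tsv",
        d / "fractions.tsv",
        d / "top_contributors.tsv",
        d / "group_summary.json",
    ]


def _run_assoc(out: Path, d: Path, p: dict, seed: int) -> list:
    fracs = _load_fractions(out)
    meta = io.read_metadata(out / "simulate" / "metadata.tsv").set_index("sample_id")
    meta = meta.loc[fracs.sample_ids]
    results = []
    for trait in p["traits"]:
        if trait not in meta.columns:
            raise ValueError(f"trait {trait!r} not in metadata")
        results.append(association.es_trait_regression(fracs, meta[trait], trait_name=trait))
    res = pd.concat(results, ignore_index=True)
    res.to_csv(d / "associations.tsv", sep="\t", index=False)
    contrast = association.group_contrast(fracs, meta[p["group"]].to_numpy())
    contrast.to_csv(d / "group_contrast.tsv", sep="\t", index=False)
    return [d / "associations.tsv", d / "group_contrast.tsv"]


def _run_h2(out: Path, d: Path, p: dict, seed: int) -> list:
    fracs = _load_fractions(out)
    meta = io.read_metadata(out / "simulate" / "metadata.tsv").set_index("sample_id")
    meta = meta.loc[fracs.sample_ids].reset_index()
    geno = io.read_genotypes_tsv(out / "simulate" / "genotypes.tsv")
    keep = [i for i, s in enumerate(geno.individual_ids) if s in set(fracs.sample_ids)]
    geno = _subset_individuals(geno, keep)
    clean = genetics.snp_qc(geno, maf_min=p["maf_min"], missing_max=p["missing_max"])
    grm = genetics.vanraden_grm(clean)
    X, _ = genetics.build_design(meta, factors=p["factors"], covariates=p["covariates"])
    summaries = {}
    for i, es in enumerate(fracs.es_names):
        post = genetics.gblup_gibbs(
            fracs.fractions[i],
            X,
            grm,
            n_iter=p["n_iter"],
            burn_in=p["burn_in"],
            thin=p["thin"],
            prior_df=p["prior_df"],
            seed=seed + i,
        )
        summaries[es] = genetics.h2_summary(post)
    io.write_json(summaries, d / "h2_summary.json")
    return [d / "h2_summary.json"]


def _subset_individuals(geno, idx):
    from .types import GenotypeMatrix

    return GenotypeMatrix(
        dosages=geno.dosages[idx],
        snp_ids=list(geno.snp_ids),
        individual_ids=[geno.individual_ids[i] for i in idx],
    )


_RUNNERS = {
    "simulate": _Stage(lambda out: [], _run_simulate),
    "preprocess": _Stage(lambda out: [out / "simulate" / "counts.tsv"], _run_preprocess),
    "rank": _Stage(lambda out: [out / "preprocess" / "relabund.tsv"], _run_rank),
    # rank.json participates in the fit checksum when the rank stage ran,
    # so a changed rank selection invalidates the cached fit
    "fit": _Stage(
        lambda out: [out / "preprocess" / "relabund.tsv"]
        + ([out / "rank" / "rank.json"] if (out / "rank" / "rank.json").exists() else []),
        _run_fit,
    ),
    "characterize": _Stage(
        lambda out: [out / "fit" / "W.tsv", out / "fit" / "H.tsv"], _run_characterize
    ),
    "assoc": _Stage(
        lambda out: [out / "fit" / "H.tsv", out / "simulate" / "metadata.tsv"], _run_assoc
    ),
    "h2": _Stage(
        lambda out: [out / "fit" / "H.tsv", out / "simulate" / "genotypes.tsv"], _run_h2
    ),
}
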