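"""End-to-end orchestration: data -> statistics -> model tests -> reports.

A run is described by a single YAML config holding either a synthetic-data
block or paths to real inputs, the rate set, the refugium hypotheses to
test and the simulation/permutation effort.  Every stage writes
tab-delimited reports into the output directory and a JSON manifest
records every parameter and seed, so identical configs reproduce
byte-identical machine-readable outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .dbrda import forward_selection, gower_center
from .demography import (classic_skyline, exp_growth_ml, growth_significance,
                         parametric_bootstrap_growth)
from .models import (GeneTree, RateSet, SUBREGION_OF_DEME, build_model,
                     theta_to_ne)
from .msat import assignment_exclusion, genetic_distances, locus_summaries, \
    summaries_frame
from .seqstats import distance_matrices, fu_fs, fu_li_d_star, \
    polymorphism_summary, UndefinedStatisticError
from .sorting import null_distribution, observed_s, test_model
from .synthetic import (SyntheticStudyConfig, simulate_env_table,
                        simulate_microsats, simulate_sequences, write_fixtures)

logger = logging.getLogger("skyisland.pipeline")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Validated pipeline configuration (see ``RunConfig.from_yaml``)."""

    output_dir: Path
    seed: int = 0
    theta_total: float = 0.0467
    rates: RateSet = field(default_factory=RateSet)
    hypotheses: list[str] = field(default_factory=lambda: [
        "single", "two_refugia", "three_refugia"])
    n_sims: int = 2000
    n_perm: int = 999
    env_effect: float = 2.0
    n_growth_replicates: int = 5
    synthetic: SyntheticStudyConfig | None = None
    inputs: dict[str, Path] | None = None

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("exactly one of a synthetic block or real input "
                             "paths must be present")
        if self.inputs is not None:
            missing = [str(p) for p in self.inputs.values() if not Path(p).exists()]
            if missing:
                raise FileNotFoundError(f"missing input files: {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        rates = RateSet(**raw.get("rates", {}))
        syn = raw.get("synthetic")
        synthetic = None
        if syn is not None:
            synthetic = SyntheticStudyConfig(**{**syn, "rng_seed": raw.get("seed", 0)})
        inputs = None
        if raw.get("inputs"):
            inputs = {k: Path(v) for k, v in raw["inputs"].items()}
        return cls(
            output_dir=Path(raw["output_dir"]),
            seed=int(raw.get("seed", 0)),
            theta_total=float(raw.get("theta_total", 0.0467)),
            rates=rates,
            hypotheses=list(raw.get("hypotheses",
                                    ["single", "two_refugia", "three_refugia"])),
            n_sims=int(raw.get("n_sims", 2000)),
            n_perm=int(raw.get("n_perm", 999)),
            env_effect=float(raw.get("env_effect", 2.0)),
            n_growth_replicates=int(raw.get("n_growth_replicates", 5)),
            synthetic=synthetic,
            inputs=inputs,
        )


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


@_stage("data")
def _load_data(config: RunConfig, rng: np.random.Generator) -> dict:
    mu_locus = config.rates.mu_site_combined * config.rates.generation_time
    total_ne = theta_to_ne(config.theta_total, mu_locus)
    if config.synthetic is not None:
        model = build_model("single", total_ne=total_ne,
                            deme_sizes=config.synthetic.deme_sizes)
        aln, tree = simulate_sequences(model, config.synthetic, rng)
        genotypes = simulate_microsats(model, config.synthetic, rng)
        predictors, latent = simulate_env_table(
            list(config.synthetic.deme_names), config.env_effect, rng)
        fixtures = write_fixtures(
            {"alignment": aln, "gene_tree": tree, "genotypes": genotypes,
             "predictors": predictors, "config": config.synthetic},
            config.output_dir / "fixtures")
        deme_sizes = dict(config.synthetic.deme_sizes)
        return {"alignment": aln, "genealogy": tree, "genotypes": genotypes,
                "predictors": predictors, "deme_sizes": deme_sizes,
                "total_ne": total_ne, "fixtures": fixtures}
    paths = config.inputs
    deme_of_sample, _sub = sio.read_metadata(paths["metadata"])
    aln = sio.read_fasta_alignment(paths["fasta"], deme_of_sample)
    genotypes = sio.read_genotypes(paths["genotypes"]) if "genotypes" in paths else None
    predictors = sio.read_predictors(paths["predictors"]) if "predictors" in paths else None
    genealogy = None
    if "observed_tree" in paths:
        genealogy = GeneTree.from_dendropy(
            sio.read_newick(paths["observed_tree"]), deme_of_sample)
    sizes: dict[str, int] = {}
    for s in aln.sample_ids:
        sizes[aln.deme_of_sample[s]] = sizes.get(aln.deme_of_sample[s], 0) + 1
    return {"alignment": aln, "genealogy": genealogy, "genotypes": genotypes,
            "predictors": predictors, "deme_sizes": sizes, "total_ne": total_ne}


@_stage("seqstats")
def _run_seqstats(data: dict, outdir: Path) -> dict:
    aln = data["alignment"]
    rows = [s.as_row() for s in polymorphism_summary(aln, "per-deme")]
    rows += [s.as_row() for s in polymorphism_summary(aln, "all")]
    table1 = pd.DataFrame(rows)
    try:
        fs = fu_fs(aln)
    except UndefinedStatisticError:
        fs = np.nan
    try:
        dstar = fu_li_d_star(aln)
    except UndefinedStatisticError:
        dstar = np.nan
    neut = pd.DataFrame([{"statistic": "fu_fs", "value": fs},
                         {"statistic": "fu_li_d_star", "value": dstar}])
    pdist = distance_matrices(aln, "p-distance")
    phist = distance_matrices(aln, "phi_st")
    table1.to_csv(outdir / "seq_polymorphism.tsv", sep="\t", index=False)
    neut.to_csv(outdir / "seq_neutrality.tsv", sep="\t", index=False)
    sio.write_distance_matrix(pdist, outdir / "dist_pdistance.tsv")
    sio.write_distance_matrix(phist, outdir / "dist_phist.tsv")
    return {"table1": table1, "neutrality": neut, "pdist": pdist, "phist": phist}


@_stage("msatstats")
def _run_msatstats(data: dict, outdir: Path, n_sim: int,
                   rng: np.random.Generator) -> dict:
    gt = data["genotypes"]
    if gt is None:
        return {}
    table3 = summaries_frame(locus_summaries(gt))
    nei = genetic_distances(gt, "nei_standard")
    fst = genetic_distances(gt, "fst")
    assign = assignment_exclusion(gt, n_sim=n_sim, rng=rng)
    table3.to_csv(outdir / "msat_summaries.tsv", sep="\t", index=False)
    sio.write_distance_matrix(nei, outdir / "dist_nei.tsv")
    sio.write_distance_matrix(fst, outdir / "dist_fst.tsv")
    assign.to_csv(outdir / "assignment.tsv", sep="\t", index=False)
    return {"table3": table3, "nei": nei, "fst": fst, "assignment": assign}


@_stage("sorting_test")
def _run_sorting(data: dict, config: RunConfig, outdir: Path,
                 rng: np.random.Generator) -> pd.DataFrame:
    genealogy = data["genealogy"]
    if genealogy is None:
        raise ValueError("sorting test requires an observed genealogy")
    s_obs = observed_s(genealogy)
    rows = []
    for hyp in config.hypotheses:
        model = build_model(hyp, total_ne=data["total_ne"],
                            deme_sizes=data["deme_sizes"])
        null = null_distribution(model, data["deme_sizes"], config.n_sims, rng)
        res = test_model(s_obs, null, model_name=hyp, seed=config.seed)
        logger.info("%s", res)
        rows.append({"model": hyp, "null_mean_S": res.null_mean,
                     "null_sd_S": res.null_sd, "observed_S": res.observed_s,
                     "p_value": res.p_value, "n_sims": res.n_sims,
                     "rejected_at_0.05": res.rejected})
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "sorting_test.tsv", sep="\t", index=False)
    return table


@_stage("dbrda")
def _run_dbrda(data: dict, config: RunConfig, outdir: Path,
               rng: np.random.Generator, phist: pd.DataFrame) -> pd.DataFrame | None:
    predictors = data["predictors"]
    if predictors is None:
        return None
    demes = [d for d in phist.index if d in predictors.data.index]
    D = phist.loc[demes, demes].to_numpy()
    table = predictors.data.loc[demes]
    from .dbrda import PredictorTable
    pt = PredictorTable(table, predictors.sets)
    result = forward_selection(gower_center(D), pt, n_perm=config.n_perm, rng=rng)
    merged = result.marginal.merge(
        result.selection.rename(columns={"P": "sequential_P"}),
        on="set", how="left")
    merged.to_csv(outdir / "dbrda.tsv", sep="\t", index=False)
    result.set_correlations.to_csv(outdir / "dbrda_set_correlations.tsv", sep="\t")
    return merged


@_stage("demography")
def _run_demography(data: dict, config: RunConfig, outdir: Path,
                    rng: np.random.Generator) -> dict:
    genealogy = data["genealogy"]
    if genealogy is None:
        return {}
    sky = classic_skyline(genealogy, n_groups=10)
    gen_time = config.rates.generation_time
    sky_df = pd.DataFrame({
        "t_lower_gen": sky.boundaries[:-1], "t_upper_gen": sky.boundaries[1:],
        "t_lower_years": sky.boundaries[:-1] * gen_time,
        "t_upper_years": sky.boundaries[1:] * gen_time,
        "ne_estimate": sky.ne})
    fit = exp_growth_ml(genealogy)
    reps = parametric_bootstrap_growth(genealogy, config.n_growth_replicates, rng)
    sig = growth_significance(reps)
    growth_df = pd.DataFrame([{
        "g_hat": fit.g, "theta0": fit.theta0,
        "mean_g_replicates": sig["mean_g"], "sd_g": sig["sd_g"],
        "growth_declared": sig["growth_declared"],
        "n_replicates": sig["n_replicates"]}])
    sky_df.to_csv(outdir / "skyline.tsv", sep="\t", index=False)
    growth_df.to_csv(outdir / "growth.tsv", sep="\t", index=False)
    return {"skyline": sky_df, "growth": growth_df}


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and assemble the report bundle.

    Returns the in-memory results keyed by stage; all reports are also
    written under ``config.output_dir`` together with ``manifest.json``
    (parameters, seeds, package version) for provenance.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(config.seed)
    keys = ["data", "msat", "sorting", "dbrda", "demography"]
    streams = dict(zip(keys, (np.random.default_rng(s)
                              for s in master.spawn(len(keys)))))

    data = _load_data(config, streams["data"])
    results: dict = {"data": {k: v for k, v in data.items()
                              if k in ("deme_sizes", "total_ne")}}
    results["seqstats"] = _run_seqstats(data, outdir)
    results["msatstats"] = _run_msatstats(data, outdir,
                                          n_sim=1000, rng=streams["msat"])
    results["sorting_test"] = _run_sorting(data, config, outdir, streams["sorting"])
    results["dbrda"] = _run_dbrda(data, config, outdir, streams["dbrda"],
                                  results["seqstats"]["phist"])
    results["demography"] = _run_demography(data, config, outdir,
                                            streams["demography"])

    from . import __version__
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "theta_total": config.theta_total,
        "total_ne": data["total_ne"],
        "hypotheses": config.hypotheses,
        "n_sims": config.n_sims,
        "n_perm": config.n_perm,
        "rates": {"mu_site_cytb": config.rates.mu_site_cytb,
                  "mu_site_combined": config.rates.mu_site_combined,
                  "locus_length": config.rates.locus_length,
                  "msat_mu": config.rates.msat_mu,
                  "generation_time": config.rates.generation_time},
        "deme_sizes": data["deme_sizes"],
        "synthetic": (None if config.synthetic is None
                      else {k: (list(v) if isinstance(v, (list, tuple)) else v)
                            for k, v in vars(config.synthetic).items()
                            if not k.startswith("_")}),
        "stages_written": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    results["manifest"] = manifest
    return results
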