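"""End-to-end orchestration: statistics → scenario choice → co-divergence test.

One YAML configuration drives the whole workflow; every stochastic stage has
its own seed and the provenance block (package version, seeds, config hash)
is written with every run so reruns are verifiable.  Logging goes to stderr;
results only ever go to files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import __version__, abc_select, habc, sumstats, synthdata
from .coalsim import load_scenario, scenario_from_dict
from .popdata import read_alignment, read_popmap

__all__ = ["run_all", "load_config"]

log = logging.getLogger("mesophylo")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _config_hash(config: Mapping) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _stats_stage(aln, assign, cfg: Mapping, out: Path) -> dict:
    rng = np.random.default_rng(cfg.get("seed", 0))
    perms = int(cfg.get("permutations", 1000))
    rows = []
    for pop in assign.populations:
        sub = aln.subset(list(assign.samples_in_population(pop)))
        if sub.n_samples < 2:
            rows.append({"population": pop, "N": sub.n_samples, "note": "n. a."})
            continue
        st = sumstats.summarize(sub)
        rows.append(
            {
                "population": pop,
                "N": st.n,
                "L": st.L,
                "S": st.S,
                "k": st.k,
                "pi": st.pi,
                "sd_pi": st.sd_pi,
                "Hd": "n. a." if st.is_na("Hd") else st.Hd,
                "sd_Hd": st.sd_Hd,
                "K_obs": st.K_obs,
                "D": "n. a." if st.is_na("D") else st.D,
                "FS": "n. a." if st.is_na("FS") else st.FS,
            }
        )
    with open(out / "stats.tsv", "w") as fh:
        keys = ["population", "N", "L", "S", "k", "pi", "sd_pi", "Hd", "sd_Hd", "K_obs", "D", "FS"]
        fh.write("\t".join(keys) + "\n")
        for r in rows:
            fh.write("\t".join(str(r.get(k, "n. a.")) for k in keys) + "\n")
    result = {"populations": len(rows)}
    if assign.n_groups >= 2:
        am = sumstats.amova(aln, assign, permutations=perms, rng=rng)
        result["amova"] = {
            "F_CT": am.f_ct,
            "F_SC": am.f_sc,
            "F_ST": am.f_st,
            "p_CT": am.p_ct,
            "p_SC": am.p_sc,
            "p_ST": am.p_st,
            "percent_variation": list(am.percent),
            "n_distinct_group_permutations": am.n_distinct_group_permutations,
        }
        with open(out / "amova.json", "w") as fh:
            json.dump(result["amova"], fh, indent=2)
    return result


def _abc_stage(aln, assign, cfg: Mapping, out: Path) -> dict:
    seed = int(cfg.get("seed", 1))
    rng = np.random.default_rng(seed)
    scenarios = []
    for item in cfg["scenarios"]:
        scenarios.append(
            load_scenario(item) if isinstance(item, (str, Path)) else scenario_from_dict(item)
        )
    priors = (
        abc_select.load_priors(cfg["priors"])
        if isinstance(cfg["priors"], (str, Path))
        else abc_select.priors_from_dict(cfg["priors"])
    )
    sim_cfg = abc_select.SimulationConfig(
        L=aln.n_sites,
        mu_param=cfg.get("mu_param", "mu"),
        kappa=float(cfg.get("kappa", 4.0)),
    )
    n_sims = int(cfg.get("n_sims", 10_000))
    tol = float(cfg.get("tolerance", 0.01))
    table = abc_select.build_reference_table(
        scenarios, priors, n_sims // len(scenarios), sim_cfg, rng
    )
    _, observed = abc_select.abc_statistics(aln, assign)
    post = abc_select.select_scenario(table, observed, tol)
    report: dict = {
        "scenarios": list(post.scenario_names),
        "rejection_pp": post.rejection_pp.tolist(),
        "regression_pp": post.regression_pp.tolist(),
        "selected": post.scenario_names[post.selected],
        "pp_ci_95": [post.ci_low, post.ci_high],
        "tolerance": tol,
        "n_accepted": post.n_accepted,
    }
    n_pods = int(cfg.get("pods", 0))
    if n_pods >= 100:
        err = abc_select.compute_error_rates(
            scenarios, priors, table, sim_cfg, rng, n_pods=n_pods, tolerance=tol
        )
        report["type1"] = err.type1.tolist()
        report["type2"] = err.type2.tolist()
    g = priors.generation_time
    params = abc_select.estimate_parameters(table, observed, priors, post.selected, tol)
    report["parameters"] = {
        name: {
            "median_generations": params.point[name]["median"],
            "mode_generations": params.point[name]["mode"],
            "ci95_generations": list(params.interval[name]),
            "median_years": abc_select.convert_generations_to_years(
                params.point[name]["median"], g
            ),
        }
        for name in params.samples
    }
    with open(out / "abc_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def _habc_stage(cfg: Mapping, out: Path) -> dict:
    seed = int(cfg.get("seed", 1))
    configs = [
        habc.PairConfig(
            label=p.get("label", f"pair{i}"),
            n1=int(p["n1"]),
            n2=int(p["n2"]),
            L=int(p["L"]),
            kappa=float(p.get("kappa", 4.0)),
            theta_upper=float(p.get("theta_upper", 0.02)),
            barrier=p.get("barrier", ""),
        )
        for i, p in enumerate(cfg["pairs"])
    ]
    if "observed" in cfg:
        observed = np.asarray(cfg["observed"], dtype=float)
    else:
        pair_alns = [
            (read_alignment(p["fasta1"]), read_alignment(p["fasta2"]))
            for p in cfg["pairs"]
        ]
        observed = habc.observed_pair_stats(pair_alns)
    post = habc.habc_posterior(
        observed,
        configs,
        n_sims=int(cfg.get("n_sims", 100_000)),
        tolerance=float(cfg.get("tolerance", 0.002)),
        seed=seed,
        tau_max=float(cfg.get("tau_max", 0.5)),
    )
    theta_ave = habc.theta_ave_of(configs)
    conv = habc.tdiv_convert(
        post.e_tau_mode,
        theta_ave,
        mu=float(cfg.get("mu", 0.0042)),
        mu_unit=cfg.get("mu_unit", "per_Myr"),
        generation_time=float(cfg.get("generation_time", 2.0)),
    )
    verdict = (
        "synchronous (Ω ≤ 0.01)" if post.synchronous else "asynchronous (Ω > 0.01)"
    )
    report = {
        "psi_pmf": post.psi_pmf.tolist(),
        "psi_mode": post.psi_mode,
        "omega_mode": post.omega_mode,
        "omega_hpd_95": list(post.omega_hpd),
        "e_tau_mode": post.e_tau_mode,
        "e_tau_hpd_95": list(post.e_tau_hpd),
        "verdict": verdict,
        "t_div_years": conv.t_div_years,
        "t_div_generations": conv.t_div_generations,
        "theta_ave": theta_ave,
        "n_accepted": post.n_accepted,
    }
    with open(out / "habc.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def run_all(config: Mapping, out_dir: str | Path | None = None) -> dict:
    """Run every configured stage; returns the combined report bundle.

    Any stage failure aborts with the stage name; outputs of completed
    stages are preserved in the output directory.
    """
    out = Path(out_dir if out_dir is not None else config.get("out_dir", "mesophylo_out"))
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(name)s: %(message)s")
    bundle: dict = {}

    inp = config.get("input", {})
    if "template" in inp:
        aln, assign, truth = synthdata.generate_study(
            synthdata.study_template(inp["template"]), int(inp.get("seed", 1)), out
        )
        bundle["input"] = {"template": truth.template, "seed": truth.seed}
    elif "fasta" in inp:
        aln = read_alignment(inp["fasta"])
        assign = read_popmap(inp["popmap"])
        assign.validate_against(aln)
        bundle["input"] = {"fasta": str(inp["fasta"]), "popmap": str(inp["popmap"])}
    else:
        aln = assign = None

    for stage, runner in (
        ("stats", lambda c: _stats_stage(aln, assign, c, out)),
        ("abc", lambda c: _abc_stage(aln, assign, c, out)),
        ("habc", lambda c: _habc_stage(c, out)),
    ):
        if stage not in config:
            continue
        if stage in ("stats", "abc") and aln is None:
            raise RuntimeError(f"stage '{stage}' needs an input alignment")
        t0 = time.perf_counter()
        log.info("stage %s: starting", stage)
        try:
            bundle[stage] = runner(config[stage])
        except Exception as exc:
            log.error("stage %s failed: %s", stage, exc)
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
        log.info("stage %s: done in %.1fs", stage, time.perf_counter() - t0)

    provenance = {
        "mesophylo_version": __version__,
        "config_hash": _config_hash(config),
        "seeds": {
            stage: config[stage].get("seed")
            for stage in ("stats", "abc", "habc")
            if stage in config
        },
    }
    bundle["provenance"] = provenance
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)
    with open(out / "report.json", "w") as fh:
        json.dump(bundle, fh, indent=2, default=str)
    return bundle
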