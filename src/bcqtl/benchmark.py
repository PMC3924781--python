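"""Built-in benchmark study: the 7-QTL double backcross scenario.

Reproduces the reference Monte Carlo experiments (Case I/II at 300 progeny
split 150:150, plus a 180-progeny design) at a configurable number of
replicates, and reduces them to the headline quantities: per-QTL power,
position/effect estimate means, epistasis FDRs, and the realized trait
heritability of the generator.
"""

from __future__ import annotations

import numpy as np

from .config import RunConfig
from .montecarlo import ExperimentDesign, run_experiment, simulate_replicates
from .simulate import seven_qtl_scenario

__all__ = ["benchmark_config", "run_benchmark", "target_values"]


def benchmark_config(seed: int = 0) -> RunConfig:
    """Monte Carlo configuration: full pipeline with shortened Gibbs chains
    (estimates stabilize well before the single-fit default lengths)."""
    return RunConfig(seed=seed, gibbs_burn=300, gibbs_iter=1200)


def run_benchmark(seed: int, n_reps: int = 50, config: RunConfig | None = None) -> dict:
    """Run the benchmark experiments and return their summary tables.

    Cases I and II run on identical replicate datasets (paired seeds); the
    180-progeny design uses an independently derived seed.
    """
    scen = seven_qtl_scenario()
    cfg = config or benchmark_config(seed)
    seed180 = int(np.random.SeedSequence((seed, 180)).generate_state(1)[0])

    datasets = simulate_replicates(scen, 150, 150, n_reps, seed)
    case_i = run_experiment(
        ExperimentDesign.for_case("I", scen, 150, 150, n_reps, seed),
        cfg, datasets=datasets,
    )
    case_ii = run_experiment(
        ExperimentDesign.for_case("II", scen, 150, 150, n_reps, seed),
        cfg, datasets=datasets,
    )
    small = run_experiment(
        ExperimentDesign.for_case("I", scen, 90, 90, n_reps, seed180), cfg
    )
    realized_h2 = float(
        np.mean([d.sim_info["realized_h2"] for d in datasets]) * 100.0
    )
    return {
        "case_I": case_i,
        "case_II": case_ii,
        "n180": small,
        "realized_h2_pct": realized_h2,
        "n_replicates": n_reps,
    }


def target_values(results: dict) -> dict:
    """Headline quantities on the scales the reference tables print."""
    st = results["case_I"]
    n = results["n_replicates"]
    main, epi = st.main, st.epistasis
    out = {
        "t1": {"value": float(main["power"].min()), "n": n},
        "t2": {"value": float(main.loc["Q1", "power"]), "n": n},
        "t3": {"value": float(main.loc["Q1", "position_cM_mean"]), "n": n},
        "t4": {"value": float(main.loc["Q1", "a_mean"]), "n": n},
        "t5": {"value": float(epi.loc["EQ1", "power"]), "n": n},
        "t6": {"value": float(epi.loc["EQ2", "power"]), "n": n},
        "t7": {"value": float(epi.loc["EQ3", "power"]), "n": n},
        "t8": {"value": float(epi.loc["EQ3", "aa_mean"]), "n": n},
        "t9": {"value": float(results["n180"].fdr_epistasis), "n": n},
        "t10": {"value": float(st.fdr_epistasis), "n": n},
        "t11": {"value": float(results["realized_h2_pct"]), "n": n},
        "t12": {"value": float(results["case_II"].main.loc["Q1", "d_mean"]), "n": n},
    }
    return out
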