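"""Replicate-level experiment harness: power, FDR and estimate summaries.

Runs the full mapping workflow over simulated replicates of a QTL scenario,
matches declared QTLs/pairs to the truth with fixed window rules, and
accumulates publication-style summary tables (mean and SD of estimates over
detecting replicates, detection power in %, pooled false discovery rates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .scan import MappingResult, map_qtls
from .simulate import ProgenyData, QtlScenario, simulate_dataset

__all__ = [
    "ExperimentDesign",
    "SummaryTable",
    "CASES",
    "simulate_replicates",
    "match_main",
    "match_pairs",
    "run_experiment",
    "case_comparison",
    "constitution_study",
]

log = logging.getLogger(__name__)

#: Case label -> (model_variant, scenario_variant)
CASES = {
    "I": ("with_epistasis", "epistasis_present"),
    "II": ("without_epistasis", "epistasis_present"),
    "III": ("with_epistasis", "epistasis_absent"),
    "IV": ("without_epistasis", "epistasis_absent"),
}


@dataclass
class ExperimentDesign:
    scenario: QtlScenario
    n1: int
    n2: int
    n_replicates: int
    seed: int = 0
    model_variant: str = "with_epistasis"
    scenario_variant: str = "epistasis_present"

    def __post_init__(self):
        if self.n1 + self.n2 <= 0:
            raise ValueError("population size must be positive")
        if self.model_variant not in ("with_epistasis", "without_epistasis"):
            raise ValueError("bad model_variant")
        if self.scenario_variant not in ("epistasis_present", "epistasis_absent"):
            raise ValueError("bad scenario_variant")

    @classmethod
    def for_case(cls, case: str, scenario, n1, n2, n_replicates, seed=0):
        mv, sv = CASES[case]
        return cls(scenario, n1, n2, n_replicates, seed, mv, sv)

    def generating_scenario(self) -> QtlScenario:
        if self.scenario_variant == "epistasis_absent":
            return self.scenario.without_epistasis()
        return self.scenario


@dataclass
class SummaryTable:
    """Per-QTL and per-pair Monte Carlo summaries."""

    main: pd.DataFrame
    epistasis: pd.DataFrame
    fdr_epistasis: float
    fdr_main: float
    n_replicates: int
    n_failures: int = 0
    details: dict = field(default_factory=dict)


def simulate_replicates(
    scenario: QtlScenario, n1: int, n2: int, n_replicates: int, seed,
    line_type: str = "DH",
) -> list:
    """Independently seeded replicate datasets (fixed counter scheme)."""
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_replicates)
    return [
        simulate_dataset(scenario, n1, n2, child, line_type=line_type)
        for child in children
    ]


def _closest(declared, chrom, pos, window):
    best, best_d = None, np.inf
    for q in declared:
        if q["chromosome"] != chrom:
            continue
        d = abs(q["position_cM"] - pos)
        if d <= window and d < best_d:
            best, best_d = q, d
    return best


def match_main(result: MappingResult, scenario: QtlScenario,
               match_window: float = 10.0, false_window: float = 20.0):
    """Match declared main-effect QTLs to the truth.

    Returns (per-true-QTL dict of matched declared rows or None,
    number of false positives, number declared)."""
    table = result.main_effects_table(scenario.n_env)
    declared = table.to_dict("records")
    matches = {}
    used = set()
    for q in scenario.main_effect_qtls():
        cands = [
            (abs(d["position_cM"] - q.position_cm), i)
            for i, d in enumerate(declared)
            if i not in used
            and d["chromosome"] == q.chromosome
            and abs(d["position_cM"] - q.position_cm) <= match_window
        ]
        if cands:
            _, i = min(cands)
            used.add(i)
            matches[q.name] = declared[i]
        else:
            matches[q.name] = None
    n_false = 0
    for d in declared:
        near_any = any(
            d["chromosome"] == q.chromosome
            and abs(d["position_cM"] - q.position_cm) <= false_window
            for q in scenario.qtls
        )
        if not near_any:
            n_false += 1
    return matches, n_false, len(declared)


def match_pairs(result: MappingResult, scenario: QtlScenario,
                match_window: float = 10.0, false_window: float = 20.0):
    """Match declared epistatic pairs to the true pairs (both members)."""
    table = result.epistasis_table(scenario.n_env)
    declared = table.to_dict("records")
    true_pairs = []
    for e in scenario.epistasis:
        qi, qj = scenario.qtl(e.qtl_i), scenario.qtl(e.qtl_j)
        true_pairs.append((e, qi, qj))

    def member_dist(d, qi, qj):
        """Best orientation distance (max over members) or inf."""
        best = np.inf
        for (ci, pi, cj, pj) in (
            (d["chromosome_i"], d["position_i_cM"], d["chromosome_j"], d["position_j_cM"]),
            (d["chromosome_j"], d["position_j_cM"], d["chromosome_i"], d["position_i_cM"]),
        ):
            if ci == qi.chromosome and cj == qj.chromosome:
                dist = max(abs(pi - qi.position_cm), abs(pj - qj.position_cm))
                best = min(best, dist)
        return best

    matches = {}
    used = set()
    for e, qi, qj in true_pairs:
        cands = [
            (member_dist(d, qi, qj), i)
            for i, d in enumerate(declared)
            if i not in used and member_dist(d, qi, qj) <= match_window
        ]
        if cands:
            _, i = min(cands)
            used.add(i)
            d = dict(declared[i])
            # orient positions to the (qtl_i, qtl_j) order of the truth
            if not (
                d["chromosome_i"] == qi.chromosome
                and abs(d["position_i_cM"] - qi.position_cm) <= match_window
                and d["chromosome_j"] == qj.chromosome
                and abs(d["position_j_cM"] - qj.position_cm) <= match_window
            ):
                d["chromosome_i"], d["chromosome_j"] = d["chromosome_j"], d["chromosome_i"]
                d["position_i_cM"], d["position_j_cM"] = (
                    d["position_j_cM"], d["position_i_cM"],
                )
            matches[e.name] = d
        else:
            matches[e.name] = None
    n_false = sum(
        1
        for d in declared
        if all(member_dist(d, qi, qj) > false_window for _, qi, qj in true_pairs)
    )
    return matches, n_false, len(declared)


def _summarize(records: dict, n_reps: int, columns: list) -> pd.DataFrame:
    if not records:
        cols = ["power"] + [f"{c}_{s}" for c in columns for s in ("mean", "sd")]
        return pd.DataFrame(columns=cols, index=pd.Index([], name="qtl"))
    rows = []
    for name, hits in records.items():
        row = {"qtl": name, "power": 100.0 * len(hits) / n_reps}
        for col in columns:
            vals = np.array([h[col] for h in hits if np.isfinite(h.get(col, np.nan))])
            row[f"{col}_mean"] = vals.mean() if vals.size else np.nan
            row[f"{col}_sd"] = vals.std(ddof=1) if vals.size > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("qtl")


def run_experiment(
    design: ExperimentDesign,
    config: RunConfig | None = None,
    datasets: list | None = None,
    thresholds: dict | None = None,
) -> SummaryTable:
    """Run the mapping workflow over Monte Carlo replicates and summarize.

    If ``config.cache_thresholds`` (default) the permutation thresholds are
    computed on the first replicate and reused for the rest.
    """
    cfg = (config or RunConfig()).replace(
        include_epistasis=design.model_variant == "with_epistasis"
    )
    scen = design.generating_scenario()
    full_scen = design.scenario  # matching is against the full truth
    n_env = full_scen.n_env

    if datasets is None:
        datasets = simulate_replicates(
            scen, design.n1, design.n2, design.n_replicates, design.seed,
            line_type=cfg.line_type,
        )
    anal_root = np.random.SeedSequence((design.seed, 0xA11A))
    anal_seeds = [int(c.generate_state(1)[0]) for c in anal_root.spawn(design.n_replicates)]

    main_hits = {q.name: [] for q in full_scen.main_effect_qtls()}
    pair_hits = {e.name: [] for e in full_scen.epistasis}
    false_main = declared_main = false_pairs = declared_pairs = 0
    n_failures = 0
    cached = dict(thresholds or {})
    results = []
    for i, data in enumerate(datasets):
        try:
            res = map_qtls(
                data,
                cfg.replace(seed=anal_seeds[i]),
                thresholds=cached if (cached and cfg.cache_thresholds) else None,
            )
        except Exception:  # noqa: BLE001 - replicate failures are counted
            log.exception("replicate %d failed", i)
            n_failures += 1
            continue
        if cfg.cache_thresholds and not cached:
            cached = dict(res.thresholds)
        results.append(res)
        m, nf, nd = match_main(res, full_scen, cfg.match_window_cm, cfg.false_window_cm)
        false_main += nf
        declared_main += nd
        for name, hit in m.items():
            if hit is not None:
                main_hits[name].append(hit)
        if cfg.include_epistasis:
            pm, pf, pdn = match_pairs(
                res, full_scen, cfg.match_window_cm, cfg.false_window_cm
            )
            false_pairs += pf
            declared_pairs += pdn
            for name, hit in pm.items():
                if hit is not None:
                    pair_hits[name].append(hit)

    n_eff = design.n_replicates - n_failures
    main_cols = ["position_cM", "a", "d"] + [
        f"{t}{h + 1}" for t in ("ae", "de") for h in range(n_env)
    ]
    pair_cols = ["position_i_cM", "position_j_cM", "aa"] + [
        f"aae{h + 1}" for h in range(n_env)
    ]
    return SummaryTable(
        main=_summarize(main_hits, max(n_eff, 1), main_cols),
        epistasis=_summarize(pair_hits, max(n_eff, 1), pair_cols),
        fdr_epistasis=false_pairs / declared_pairs if declared_pairs else np.nan,
        fdr_main=false_main / declared_main if declared_main else np.nan,
        n_replicates=n_eff,
        n_failures=n_failures,
        details={"thresholds": cached, "results": results},
    )


def case_comparison(
    scenario: QtlScenario,
    n1: int,
    n2: int,
    n_replicates: int,
    seed: int = 0,
    config: RunConfig | None = None,
    cases=("I", "II", "III", "IV"),
) -> dict:
    """Cases I-IV on paired seeds: I/II share replicate datasets, as do III/IV."""
    cfg = config or RunConfig()
    shared: dict = {}
    out = {}
    for case in cases:
        design = ExperimentDesign.for_case(case, scenario, n1, n2, n_replicates, seed)
        sv = design.scenario_variant
        if sv not in shared:
            shared[sv] = simulate_replicates(
                design.generating_scenario(), n1, n2, n_replicates, seed,
                line_type=cfg.line_type,
            )
        out[case] = run_experiment(design, cfg, datasets=shared[sv])
    return out


def constitution_study(
    scenario: QtlScenario,
    ratios=((150, 150), (100, 200), (50, 250)),
    n_replicates: int = 200,
    seed: int = 0,
    config: RunConfig | None = None,
) -> dict:
    """Case I experiments across population constitutions; keys "n1:n2"."""
    out = {}
    for n1, n2 in ratios:
        design = ExperimentDesign.for_case(
            "I", scenario, n1, n2, n_replicates, seed
        )
        out[f"{n1}:{n2}"] = run_experiment(design, config)
    return out
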