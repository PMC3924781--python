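# bcqtl

QTL mapping for **immortal double backcross populations** — panels of DH
(doubled haploid) or selfed RI lines crossed to both homozygous parents —
under a mixed linear model. The composite-interval-mapping workflow
estimates QTL positions together with additive, dominance and
additive×additive epistatic effects and their environment interactions
(QE), and ships with a gamete-level population simulator and a Monte Carlo
harness for power/FDR studies.

## What it does

1. **Probability kernel** (`bcqtl.probability`) — Haldane recombination
   arithmetic and the conditional QTL-genotype probabilities given
   flanking-marker genotypes for DH×P1, DH×P2, RI×P1 and RI×P2 progeny;
   converts them into the effect coefficients
   `x_A = p1 − p3`, `x_D = (p2 − p1 − p3)/2`, `x_AA = x_A·x_A`.
2. **Simulator** (`bcqtl.simulate`) — simulated meiosis for DH/RI line
   panels, double backcross progeny, and multi-environment phenotypes with
   residual variance calibrated to a target heritability. The built-in
   `seven_qtl_scenario()` is a 5-chromosome / 55-marker / 7-QTL / 3-pair /
   3-environment benchmark with 60% total heritability.
3. **Mixed-model core** (`bcqtl.mixedmodel`) — extra-sum-of-squares
   (Henderson III) F-tests of fixed QTL blocks with tolerance-based ranks,
   and block Gibbs sampling for the full model (fixed main/epistatic
   effects, random environment and QE blocks); a deterministic EM fallback
   is available (`estimation: em`).
4. **Genome scan** (`bcqtl.scan`) — marker-pair cofactor pre-selection
   (MPS), permutation-calibrated genome-wide thresholds, 1D scan for main
   effects, 2D scan for epistasis with declared-QTL anchoring, peak calling
   and backward-elimination model selection (`map_qtls` orchestrates).
5. **Monte Carlo harness** (`bcqtl.montecarlo`) — replicate-level
   experiments (Cases I–IV: epistasis present/absent × modeled/ignored;
   sample-size and population-constitution studies) with fixed matching
   rules for power and pooled FDR.
6. **IO + CLI** (`bcqtl.io`, `bcqtl.cli`) — plain CSV/YAML/JSON formats and
   the `bcqtl` command.

## CLI

```sh
# simulate the built-in benchmark scenario (300 progeny, 150:150)
bcqtl simulate --seed 1 --n1 150 --n2 150 --out data/

# full mapping workflow on a dataset directory (map/genotypes/phenotypes CSV)
bcqtl map data/ --n-perm 200 --alpha 0.05 --seed 1 --out results/

# single stages
bcqtl scan1d data/ --step 1 --out profile.csv
bcqtl permute data/ --kind 1d --n-perm 200 --alpha 0.05
bcqtl montecarlo --case I --reps 50 --n1 150 --n2 150 --seed 1 --out mc/
```

Exit codes: 0 ok, 2 usage, 3 data error, 4 numerical failure. All outputs
are reproducible from (inputs, config, seed); see `bcqtl.config.RunConfig`
for every tunable (YAML-loadable via `--config`).

### Dataset formats

* `map.csv` — `chromosome,marker,position_cM`
* `genotypes.csv` — `individual,origin,<marker...>`; codes 2 = P1/P1,
  1 = heterozygote, 0 = P2/P2, empty = missing; origin is `BC_P1`/`BC_P2`
* `phenotypes.csv` — `environment,individual,value` (missing records allowed)
* scenario YAML — QTL positions/effects per environment, heritability

## Notes

* Genome scans test per-environment effect blocks; QE effects are treated
  as fixed per-environment constants in the generator and as random blocks
  (one variance component each) at the estimation stage.
* The 2D epistasis stage scans pairs of candidate intervals (declared QTLs,
  1D cofactor intervals, and strictly pre-selected interval pairs), with
  declared-QTL positions used as anchor points; set
  `scan_2d_scope: genome` for an exhaustive pair grid.
* Thresholds can be cached across Monte Carlo replicates
  (`cache_thresholds`, default on) to keep replicate studies tractable.
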