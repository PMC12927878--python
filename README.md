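# lotic

Macroecology of bacterioplankton along continental river transects.

Large rivers carry their microbial communities downstream for weeks. Over
that water travel time (WTT) bacteria divide, get eaten, sediment out, and
are replaced by better-adapted phylotypes, so both the community's *function*
(secondary production, cell numbers) and its *composition* (richness, beta
diversity) develop along the hydrological path. `lotic` implements the
complete quantitative toolkit for analysing such transects, for microbial
ecologists working with whole-river surveys: a site-metadata table (cell
counts, secondary production, cell volumes, hydrology) plus a 16S rRNA ASV
count table in, rates and turnover estimates out.

## What it computes

**Travel time.** A transect is a downstream-ordered chain of sites; each
segment's WTT is distance / flow velocity and `tt_cum` is the prefix sum —
the time axis on which bacterial generations accumulate.

**Production calculus** (per site, then per segment, then whole river), in
the field's standard notation:

    BSP_c  = BSP * 1e9 / TCC                 cell-specific production, fgC cell⁻¹ h⁻¹
    mBM_c  = 310 fgC µm⁻³ * mV_c             cell biomass from mean cell volume
    CD_d   = 24 * BSP_c / mBM_c              daily cell division rate
    T_d    = 1 / CD_d                        doubling time (reciprocal convention)
    aCP_h  = mean(BSP_up, BSP_down) * 1e9 / mBM_c,up     segment cell production
    CP_tot = Σ aCP_h * tt_segment            cells produced per litre over the river

plus cumulative doubling events `CD_d,median × tt_cum` (the number of
generations species sorting can act on), the ratio of `CP_tot` to the median
standing stock (everything above ~1 was lost to grazing, die-off and
sedimentation), and the conversion of per-cell carbon rates into atoms per
cell per hour (`× N_A / M_C`).

**Diversity.** Libraries are screened, rarefied by repeated resampling with
replacement (50 repetitions, averaged and rounded), and summarised as
observed-ASV richness, Bray–Curtis dissimilarities, and the additive
partition of pairwise Sørensen dissimilarity into Simpson *turnover*
(replacement) and *nestedness* (loss):

    β_sim = min(b,c) / (a + min(b,c)),  β_sor = (b+c) / (2a+b+c),  β_nes = β_sor − β_sim

with whole-river summaries (endpoint pair or Baselga multiple-site) and a
headwater-persistence analysis (which fraction of the ASVs seeded by the
uppermost sites is still present in ≥90 % of downstream samples).

**Trends and growth.** OLS trend models with slope ± SE and adjusted R²,
backward-selection multiple regression, PCoA/nMDS ordination with
permutation-based environmental vector fitting, a discharge-ratio richness
model (slope per *doubling* of discharge), and phylotype-level growth:
penalized cubic-spline smooths of absolute abundance (relative abundance ×
TCC) against travel time, analytic derivatives with credible envelopes,
derivative extrema, and site-to-site per-capita rates compared to the bulk
division rate.

**Synthetic data.** A generator with fully known ground truth (planted TCC /
BSP / richness slopes, a persistent headwater core, per-segment phylotype
replacement, logistic "bloomers" ~100× faster than the bulk) emulating the
statistical structure of the Joint Danube Survey datasets; every analysis
stage is tested by recovering what the generator planted.

## Worked example

```
lotic run --preset jds3like --seed 1 --reps 10 --out out/
```

generates a 54-site low-flow river (≈2563 km, velocities 0.9–5.4 km h⁻¹)
and runs the whole pipeline. Headline output (abridged `report.json`):

```json
{
  "total_travel_time_days": 49.34,
  "median_doubling_time_days": 8.38,
  "cumulative_divisions": 5.89,
  "cp_tot_cells_per_l": 7.88e10,
  "standing_stock_ratio": 6.24,
  "whole_river_turnover": 0.836,
  "turnover_contribution_pct": 95.5,
  "headwater_persistence": 0.10,
  "richness_slope_asv_per_h": -0.1238,
  "tcc_slope_cells_per_l_h": 1.05e7
}
```

Read: one litre of water takes ~49 days to traverse the river; the median
cell doubles every ~8.4 days, so a cell lineage experiences ~5.9 doublings
en route; ~7.9 × 10¹⁰ cells are produced per litre along the way — 6.2× the
median standing stock, so ~84 % of production is lost in transit; the
endpoint communities share little (turnover 0.84, 95 % of beta diversity),
only 10 % of headwater ASVs persist downstream, and richness declines by
~0.12 ASVs per travel-hour (the planted truth is −0.13 ± recovery error,
and +9.5 × 10⁶ cells l⁻¹ h⁻¹ for TCC).

The same stages are available as library calls (`lotic.production.build_profile`,
`lotic.diversity.beta_partition_pair`, `lotic.asv_growth.fit_smoother`, ...)
and as per-stage subcommands (`lotic simulate`, `lotic production`,
`lotic diversity`).

## Layout

```
src/lotic/transect.py     sites, segments, travel times, discharge ratios
src/lotic/production.py   the production calculus
src/lotic/diversity.py    ASV tables, rarefaction, beta partition, persistence
src/lotic/trends.py       OLS, backward selection, ordination, vector fit
src/lotic/asv_growth.py   selection filters, spline smooths, derivatives
src/lotic/synthetic.py    ground-truth river generator (presets)
src/lotic/pipeline.py     end-to-end runner; cli.py: command-line interface
docs/methods.md           models, assumptions, parameter choices, limits
```
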