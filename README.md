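# surfassoc

Surface-association behaviour of archival-tagged tropical tuna.

Juvenile bigeye (*Thunnus obesus*) and yellowfin (*T. albacares*) tuna
aggregate around floating objects — above all man-made fish aggregating
devices (FADs) — where they are vulnerable to purse-seine fisheries.
Archival tags record depth and ambient water temperature for months at a
time, and sustained occupancy of warm shallow water is a behavioural
signature of this association.  `surfassoc` turns raw per-fish tag records
into quantitative surface-association metrics and maps:

1. **Preprocessing** — series are screened (≥ 30 days, no gap over 1 h) and
   reduced to 3-hour bins of *diving amplitude* (SD of depth, m) and
   *thermal habitat* (mean water temperature, °C).
2. **Behavioural classification** — a two-state multivariate-normal hidden
   Markov model is fitted per individual by Baum–Welch EM on the bivariate
   binned series $y_t = (\mathrm{SD}_t,\ \bar T_t)$:

   $$y_t \mid S_t = k \sim \mathcal N(\mu_k, \Sigma_k),\qquad
     P(S_{t+1}=j \mid S_t=i) = A_{ij},\quad k,i,j \in \{\text{shallow},
     \text{deep}\}.$$

   The state with the warmer mean thermal habitat is labelled *shallow*;
   forward–backward smoothing gives $P(S_t = \text{shallow} \mid y_{1:T})$
   at every bin (missing bins are bridged as censored observations).
3. **Surface-association probability** — a trailing 24-hour running mean
   (eight 3-hour bins) of the smoothed shallow-state probability.  Diel
   vertical switching (12 h shallow by night, 12 h deep by day) sits at
   exactly 0.5; sustained shallow residence approaches 1.
4. **Events and metrics** — maximal runs with the running mean above a
   threshold (default 0.75) are surface-association events; per-fish
   summaries include proportion of time surface-associated, events per
   month-at-liberty, release and recapture event flags, 1.5 × IQR
   duration outliers, a 0.01–0.99 threshold sweep, and Hartigan's dip
   test of bimodality for the final-24-hour probabilities.
5. **Spatial combination** — light-based geolocation estimates carry
   axis-aligned 95 % confidence ellipses; each ellipse inherits the
   probability of its nearest 3-hour bin and is rasterized onto a 0.1°
   grid, with all (ellipse, cell) observations averaged per map cell.

Real tag archives of this kind are distributed on request only, so the
package ships a synthetic-data generator (`surfassoc.synthetic`) that
emulates the assumed structure — diel switching, planted bouts, thermal
stratification, data gaps, random-walk tracks — and retains full generator
truth for oracle testing.

## Worked example

```python
import surfassoc as sf

scen = sf.SimScenario(n_fish=3, seed=5, duration_days_range=(40, 50))
sf.simulate_cohort(scen, "demo", with_tracks=True)
res = sf.run_pipeline(sf.RunConfig(rng_seed=1), "demo", out_dir="demo_out")
print(res.summary[["fish_id", "species", "n_events",
                   "prop_surface_associated", "events_per_month",
                   "has_release_event", "final24_mean_sa"]].round(3))
```

prints

```
fish_id   species  n_events  prop_surface_associated  events_per_month  has_release_event  final24_mean_sa
 sim000    bigeye         2                    0.065             1.268              False            0.500
 sim001 yellowfin         5                    0.237             3.238               True            0.906
 sim002    bigeye         3                    0.455             2.174               True            0.500
```

`sim000` shows mostly diel behaviour (6.5 % of time in events, final-day
probability pinned at the diel 0.5); `sim001` started a surface-association
bout at release and was still surface-associated in its final 24 h (0.906);
`sim002` carried a 13-day post-release association.  `demo_out/` holds tidy
CSVs (`summary`, `events`, `sweep`, `posteriors`, `exclusions`), fitted
models as JSON, and the combined 0.1° raster (`raster.csv`: lon, lat,
mean_probability, n_obs — 748 cells in this run).

The same pipeline is available from the shell:

```sh
surfassoc simulate --out demo --seed 5
surfassoc run --input demo --out demo_out
surfassoc sweep --input demo --out demo_sweep.csv
```

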