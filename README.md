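# agroclim

Agro-climatic feasibility analysis for high-latitude regions from gridded
monthly climate series. The pipeline takes per-model monthly temperature and
precipitation on a regular lat-lon grid (0.5° by default) and produces:

- **Pentad climatologies** — month-wise means over 5-year windows, labelled by
  the window end year (e.g. 2099 = 2095–2099).
- **Growing degree days (GDD₅)** — annual heat sums from monthly means using
  days-per-month multipliers on a 365-day calendar, with strict `> 5 °C` month
  inclusion and no upper cap, plus inclusive `GDD₅ ≥ 1200` feasibility masks.
- **Thornthwaite PET and water balance** — monthly potential
  evapotranspiration with day lengths snapped to 5° latitude intervals
  (exact-latitude mode available), May–October precipitation − PET balances,
  and p/PET aridity classification (arid where `< 0.65`).
- **Ensemble statistics** — equal-weight (1/N) multi-model means, min/max
  ranges, inter-model coefficient of variation (sample sd), and an
  F-test + pooled-variance t-test comparison between scenario families.
- **Zonal accounting and edge shifts** — feasible areas (10⁶ km², spherical
  cell areas, R = 6371 km) and percentages per region and 5° latitude band,
  area gains versus a baseline, and per-longitude leading-edge latitudes with
  northward shift distances in meridional km.

A seeded synthetic pseudo-GCM generator (latitudinal gradient, seasonal
cycle, per-model warming trends and offsets, optional cell noise, plus
pseudo-boreal/country/continent masks) stands in for real climate-model
output and doubles as the test oracle: its daily-resolution companion series
validate the monthly GDD approximation, and its analytic structure lets the
measured edge shift be checked against ΔT/|g| exactly.

## CLI

```sh
# generate a small pseudo-ensemble plus masks
agroclim synth --resolution 2 --n-models 3 --start-year 2040 --end-year 2099 \
    --seed 1 --out-dir scratch/synth

# GDD fields + feasibility masks for selected pentads
agroclim gdd scratch/synth/model_0_temperature.nc --pentads 2054,2099 \
    --out-dir scratch/gdd

# Thornthwaite PET and May–October water balance
agroclim pet scratch/synth/model_0_temperature.nc --pentad 2054 --out scratch/pet.nc
agroclim wb scratch/synth/model_0_temperature.nc \
    scratch/synth/model_0_precipitation.nc --pentad 2054 --out scratch/wb.nc

# ensemble mean/min/max/CV and scenario comparison
agroclim ensemble stats scratch/gdd/model_*_gdd_2054.nc --out scratch/ens.nc
agroclim ensemble compare emission.csv transient.csv

# zonal areas and leading-edge shift
agroclim zonal scratch/gdd/model_0_temperature_gdd_2054.nc \
    scratch/synth/mask_boreal.nc --out scratch/zonal.csv
agroclim shift scratch/gdd/model_0_temperature_gdd_2054.nc \
    scratch/gdd/model_0_temperature_gdd_2099.nc --out scratch/shift.csv
```

Grids are cell-center registered; longitudes live in [−180, 180). Missing
data propagate strictly: any missing month in a pentad window makes the cell
missing downstream, and ensemble statistics use the intersection of
non-missing members by default.

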