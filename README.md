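# ecosec — landscape ecological-security assessment

`ecosec` is a Python toolkit for assessing the **landscape ecological
security** of a region from categorical land-use rasters, aimed at
landscape ecologists and spatial planners studying resource-city fringes
(oilfield districts, mining belts) where land degradation concentrates.

It implements a complete, reproducible pipeline:

1. **DPSIR composite index.** Eleven indicators organized in the
   Driving-forces / Pressure / State / Impact / Response framework are
   computed per year on a 1 × 1 km assessment grid — among them the
   grassland degradation and restoration intensities
   `K₁ = ΔS₁/(S·Δt)`, `K₂ = ΔS₂/(S·Δt)` from land-use transfer matrices,
   the ecological risk index `ERI = Σᵢ (Aᵢ/A)·Eᵢ·Fᵢ`, ecological
   resilience `ECO = Σᵢ Aᵢ·Pᵢ/Cᵢ` (with fragmentation `Cᵢ = Nᵢ/Aᵢ`), and
   the ecosystem service value `ESV = Σᵢ Aᵢ·VCᵢ`. Indicators are min-max
   normalized with polarity and aggregated with AHP-style weights into a
   security index in [0, 1].
2. **Spatial autocorrelation.** Global Moran's I
   `I = ΣᵢΣⱼ wᵢⱼ(xᵢ−x̄)(xⱼ−x̄) / (S² ΣᵢΣⱼ wᵢⱼ)` with analytic
   randomization variance and a permutation test, and local Getis–Ord Gi*
   z-scores graded into seven hot/cold classes, including an "optimized"
   variant that selects the analysis scale by incremental spatial
   autocorrelation and controls the false discovery rate
   (Benjamini–Hochberg).
3. **Time–space zoning.** Hotspot fields from two assessment years plus
   the optimized field are overlaid into warning zones (core/key
   restoration, risk prevention, risk supervisory, ecological potential)
   and protection seeds; a resistance surface (0.5 · land-use rank +
   0.5 · zone rank, both in 1–8) feeds a minimum-cumulative-resistance
   cost distance `MCR = min Σ Dᵢⱼ·Rᵢ` (exact Dijkstra on the 8-connected
   cell graph) that delineates the protection area, with construction
   land and farmland inside it flagged as ecological conflict.
4. **Synthetic scenarios.** A seeded generator produces multi-year
   8-class landscapes with a contiguous low-security "oilfield strip",
   stepwise salinization, optional post-policy grassland restoration and
   a matching socio-economic table, so the full pipeline is testable
   without any external data.

## Worked example

```python
from ecosec import PipelineConfig, run_pipeline

res = run_pipeline(PipelineConfig(scenario="degrade_only", output_dir="out"))
print(res.moran_summary.round(6).to_string(index=False))
print(res.areas[["warning_total_km2", "protection_total_km2"]])
```

prints (deterministically, for the shipped preset seed):

```
 year  morans_i  expected_index  variance   z_score  p_value
 1980  0.135485       -0.003922  0.000695  5.288720    0.001
 1990  0.165059       -0.003922  0.000694  6.416023    0.001
 2000  0.255381       -0.003922  0.000695  9.836292    0.001
 2010  0.315430       -0.003922  0.000695 12.110709    0.001
 2017  0.352417       -0.003922  0.000695 13.513154    0.001

warning_total_km2        47.00
protection_total_km2    192.34
```

Reading the output: the security-index field is significantly clustered
every year (positive Moran's I, permutation p = 0.001 at 999
permutations), and the clustering *strengthens* over time (I: 0.135 →
0.352) as the salinizing oilfield strip develops into a coherent
low-security block. The final overlay classifies 47 km² of the 256-km²
scene as risk warning zones (dominated by 30 km² of core restoration
inside the strip) and 192 km² as protection zones around the
high-security grassland sources. `out/` contains the land-use and index
rasters per year (ESRI ASCII grid), tidy indicator/index CSVs, the Moran
summary, graded hotspot tables, the zone raster, the area report and a
`manifest.json` that fully reproduces the run.

The CLI wraps the same calls:

```bash
ecosec presets
ecosec simulate --preset degrade_only --out scenario/
ecosec run --preset degrade_only --out results/
```

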