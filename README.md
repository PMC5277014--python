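# seedphys

Analysis pipeline for cottonseed development and productivity under
contrasting crop-management systems: photo-thermal driving forces, embryo
growth kinetics, yield-component arithmetic, and information-theoretic
screening of the carbohydrate-metabolism variables that track seed weight.

It is written for crop physiologists and agronomists who have (or want to
emulate) a two-year factorial field trial — conventional management (CM)
versus integrated management strategies (IMS) at two soil fertility levels —
with daily weather records, embryo weight time courses, plot-level harvests
and a per-sample biochemistry table.

## What it computes

**Photo-thermal product (PTP).**  The seasonal driving force of seed growth,

    PTP = Σᵢ PARᵢ · RTEᵢ        [MJ m⁻²],

where PARᵢ = 0.5 × daily solar radiation and RTEᵢ = 0.5·RTE(T_avg) +
0.25·RTE(T_max) + 0.25·RTE(T_min).  RTE(T) is a beta-type cardinal-temperature
response, zero at the base (15 °C) and ceiling (35 °C) and one at the optimum
(30 °C) for seed development.

**Rapid-accumulation growth traits.**  Embryo weight vs days after anthesis
(DAA) is fitted with the logistic W(t) = W_a / (1 + e^{−k(t−t_m)}).  The
rapid-accumulation phase is bracketed by the inflection points of the growth
*rate*, DAA₁,₂ = t_m ∓ ln(2+√3)/k; its duration and the peak rate k·W_a/4
satisfy the identity duration × peak rate = 0.65848 · W_a.  Seed volume is
estimated from width W and length L as V = ⅓π(W/2)²L + ⁴⁄₃π(W/2)³.

**Yield decomposition.**  Cottonseed yield = boll density × seeds per boll ×
seed weight; oil and protein yields = seed yield × embryo fraction × embryo
oil/protein content (Kjeldahl N × 6.25).  CM-vs-IMS contrasts are reported
under both denominator conventions: increase over CM, 100(IMS−CM)/CM, and
changing amplitude, 100(IMS−CM)/IMS.

**Node significance.**  Each biochemical variable is discretized into
equal-frequency tertiles and scored against discretized 100-seed weight with
the plug-in mutual information: NMI% = 100·MI/H(target), relative
significance = NMI/max NMI, and the likelihood-ratio independence test
G = 2ΣO·ln(O/E) = 2N·MI_nats.

**Treatment testing.**  Balanced three-way fixed-effects ANOVA
(Year × Fertility × Management) with Fisher-LSD letter displays.

**Synthetic data.**  `seedphys.simulate` generates all four input kinds
(seasonal weather, logistic growth series, factorial harvest plots, an
effect-ladder biochemistry table) with known ground truth, so the whole
pipeline is testable without any field data.

## Worked example

```sh
seedphys simulate --out demo --seed 42
seedphys ptp --weather demo/weather.csv --start 2012-06-20 --end 2012-08-04 --out /dev/null
# cumulative_ptp_mj_m2: 371.204
seedphys growth --obs demo/growth.csv
```

The growth command prints one row per group (digits truncated here):

```
group,daa1,daa2,duration,peak_rate,w_asym,r2
default,20.1439,34.0699,13.9260,0.2943,6.2238,0.9921
```

i.e. rapid embryo-weight accumulation starts at ~20 DAA, ends at ~34 DAA
(duration 13.9 d), peaks at 0.294 g d⁻¹, and the fitted asymptotic 100-embryo
weight is 6.22 g (generating truth: 6 g, k = 0.2 d⁻¹, t_m = 27 d plus noise) —
note 13.926 × 0.294 ≈ 0.658 × 6.224.  Ranking the synthetic biochemistry
table against seed weight:

```sh
seedphys netsig --data demo/biochem.csv
```

```
node,mi_bits,nmi_pct,relative_significance,g_stat,df,p_value   (digits truncated)
susy,1.318,83.153,1.000,175.399,4,0.0
d_fructose,0.933,58.844,0.708,124.123,4,0.0
c_inv,0.712,44.925,0.540,94.762,4,0.0
...
```

Sucrose synthase activity explains the largest share of the seed-weight
entropy and tops the ranking, matching the generator's effect ladder; G is
exactly 2·96 times the mutual information in nats.

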