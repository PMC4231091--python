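# premap

Paramagnetic relaxation enhancement (PRE) NMR analysis for spin-labeled
protein complexes: from paired paramagnetic/diamagnetic peak intensities
to per-residue PRE rates, label-to-residue distances, calcium-state
comparisons and crystal-structure reference distances — plus a seeded
synthetic-data generator so the entire pipeline can be validated without
any experimental spectra.

The package was built around the classic PRE mapping experiment on the
cardiac troponin C–troponin I binary complex: a nitroxide label (MTSL)
is attached to an engineered cysteine on the unlabeled chain, and the
broadening of ¹⁵N-chain amide resonances reports the distance between
each residue and the label, with and without Ca²⁺. Everything is generic
over label sites, chains, and regions.

## The model

For a single evolution time point *t*, the intensity ratio of an amide
peak between the paramagnetic and diamagnetic states is

```
I_para / I_dia = R₂ · exp(−Γ₂·t) / (R₂ + Γ₂)
```

where `R₂ = π·Δν₁/₂` is the intrinsic transverse relaxation rate
(estimated from the diamagnetic linewidth, full width at half height)
and `Γ₂` is the transverse PRE rate. `Γ₂` converts to the electron–proton
distance *r* through a simplified Solomon–Bloembergen relation

```
Γ₂ = (K / r⁶) · (4τc + 3τc / (1 + ωH²τc²))
```

with `K = 1.23×10⁻³² cm⁶ s⁻²` (nitroxide spin constant), `τc` the
effective correlation time of the electron–proton vector (default 16 ns)
and `ωH` the proton Larmor angular frequency (default 600 MHz field).
Both relations are strictly monotone: the first is inverted numerically
(bracketed bisection), the second in closed form. Peaks broadened beyond
detection are assigned a floor ratio (default 0.05) and yield
lower-bound rates / upper-limit distances; ratios indistinguishable from
1 yield lower-limit distances. The usable ("quantifiable") window with
5% ratio uncertainty is roughly 12–25 Å.

## Worked example

Simulate a two-state experiment (label bound near one lobe, released
10 Å toward the other on Ca²⁺ removal), then run the analysis chain:

```
$ premap simulate --seed 7 --out-dir demo --assignment-fraction 0.45
wrote 4 peak lists and scenario.json to demo

$ premap distances --para demo/paramagnetic_plusCa.list \
    --dia demo/diamagnetic_plusCa.list --condition plusCa \
    --label-site 151 --out demo/distances_plus.tsv
$ head -9 demo/distances_plus.tsv
# premap 0.1.0
# t_evolution=0.01 s  tau_c=1.6e-08 s  spectrometer=600.0 MHz
# K=1.23e-32 cm6.s-2  floor_ratio=0.05  r2_default=50.0 s-1  r_window=12.0-25.0 A
residue_id	ratio	flag	gamma2	r	r_lo	r_hi	window
2	0.1465	ok	94.3454	14.2422	14.1656	14.3171	quantifiable
5	0.1194	ok	91.6402	14.3114	14.2368	14.3843	quantifiable
7	0.0802	ok	103.4953	14.0241	13.9586	14.0879	quantifiable
10	0.1052	ok	103.9951	14.0129	13.9450	14.0791	quantifiable
11	0.0903	ok	107.9488	13.9260	13.8611	13.9892	quantifiable
```

Each row is one residue: its intensity ratio, the PRE rate `gamma2`
(s⁻¹) solved from that ratio, and the distance `r` (Å) with its
uncertainty band (`r_lo`, `r_hi`, from the 5% ratio uncertainty). The
residues near the bound label sit ~14 Å away, comfortably inside the
quantifiable window.

Comparing the two calcium states region by region:

```
$ premap compare --para-plus demo/paramagnetic_plusCa.list \
    --dia-plus demo/diamagnetic_plusCa.list \
    --para-minus demo/paramagnetic_minusCa.list \
    --dia-minus demo/diamagnetic_minusCa.list \
    --label-site 151 --regions regions.tsv --out-dir demo/cmp
$ cat demo/cmp/region_summary.tsv
region	start	end	n_pairs	r_plusCa_mean	r_minusCa_mean	delta_mean	reference_mean
N_lobe_like	1	12	1	14.1033	23.1835	7.6893
C_lobe_like	101	112	2	23.0284	14.0833	-8.4733
```

`delta_mean` is `r(−Ca) − r(+Ca)` averaged over residues quantifiable in
both states: positive means the label moved away from that region upon
Ca²⁺ removal, negative toward it — here the simulated 10 Å bound→released
displacement is recovered as opposite-signed region averages
(`summarize_regions(..., table_sign=True)` renders the
`r(+Ca) − r(−Ca)` convention used in published summary tables instead).

A Monte-Carlo check of the whole pipeline at the experimental noise
level (5% ratio noise, partial assignment):

```
$ premap recover --seed 7 --replicates 20
{
  "median_abs_bias_A": 0.3018440437496684,
  "relative_rmse": 0.06804051218402325,
  "replicates": 20,
  "seed": 7
}
```

Recovered distances inside the 12–25 Å window are essentially unbiased
(median |bias| ≈ 0.3 Å) with ~7% relative RMSE.

Crystal reference distances for any structure/site combination:

```
$ premap refdist --structure data/1j1d.pdb --site 151 --site 159 \
    --observed-chain A --labeled-chain B --out ref.tsv
```

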