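# albind

Spectroscopic characterization of small-molecule binding to serum albumin.

Fluorescence, circular dichroism, and time-resolved measurements are the
workhorse desk experiments for asking how a drug candidate rides on plasma
albumin: how strongly it binds, by which mechanism it quenches the protein's
tryptophan fluorescence, which thermodynamic forces hold the complex
together, which Sudlow pocket it occupies, and what it does to the protein's
conformation. `albind` implements that entire analysis chain as a tested
Python library with a thin CLI, plus a synthetic-data generator so every
stage can be exercised — and its error behavior measured — against known
ground truth.

## The models

**Quenching.** Titration intensities (inner-filter corrected,
F_c = F_m·e^((A1+A2)/2)) are fitted to the Stern–Volmer relation

    F0/F = 1 + Kq·τ0·[Q] = 1 + Ksv·[Q]

per temperature. The bimolecular rate coefficient Kq = Ksv/τ0 (τ0 ≈ 1×10⁻⁸ s
for albumin) is compared against the diffusion ceiling ~2×10¹⁰ L mol⁻¹ s⁻¹;
that comparison, the temperature trend of Ksv, and the invariance of the
TCSPC lifetime vote on static vs dynamic quenching.

**Binding and thermodynamics.** For static quenching, the double-logarithmic
isotherm

    log₁₀((F0−F)/F) = n·log₁₀[Q] + log₁₀ Ka

gives the association constant Ka and apparent site count n; ln Ka vs 1/T
(Van 't Hoff) gives ΔH and ΔS; ΔG = ΔH − TΔS; and the signs of (ΔH, ΔS) map
onto the dominant noncovalent force class (Ross–Subramanian rules).

**Lifetimes.** TCSPC histograms are tail-fitted with 1–3 exponentials by
weighted least squares; model order is chosen by a reduced-χ² gate plus a
nested-model F-test, and the amplitude-weighted mean τ_avg = Σ τᵢαᵢ is
reported.

**Conformation.** CD ellipticity at 222 nm becomes mean residue ellipticity
MRE₂₂₂ = θ/(10·Cp·n·l) and α-helix % = (−MRE₂₂₂ − 2340)/30300 × 100;
synchronous scans (Δλ = 15/60 nm) report Tyr/Trp microenvironment shifts;
excitation–emission matrices are searched for fluorophore peaks after masking
the Rayleigh ridges. Site-marker displacement (warfarin → site I, ibuprofen →
site II) localizes the binding pocket via I(%) = 100·F2/F1.

## Worked example

Simulate a three-temperature titration of 2 µM albumin with 0–9 µM quencher
(ground truth: Ka = 4.09×10⁵ M⁻¹ at 298 K, n = 1.14, ΔH = −118.75 kJ/mol) and
run the full pipeline:

```
$ albind simulate titration --out demo
$ albind report --input demo/titration.csv --out demo/report.json
T (K)   Ksv (1e4/M)  Kq (1e12/M/s)  n      Ka (1e5/M)  dG (kJ/mol)  dH (kJ/mol)  dS (J/mol/K)
298     8.115        8.115          1.140  4.090       -32.01       -118.75      -291.06
304     3.151        3.151          1.140  1.588       -30.27
310     1.269        1.269          1.140  0.640       -28.52
quenching mechanism: static
dominant forces: vdw_hbond
```

Reading the table: Ka returns the generating constant exactly at every
temperature and decreases with T (the binding is exothermic); all Kq exceed
the 2×10¹⁰ collisional ceiling and Ksv falls with temperature, so the verdict
is static quenching by ground-state complex formation; ΔH and ΔS are both
negative, so van der Waals contacts and hydrogen bonds dominate, and ΔG is
negative throughout (spontaneous binding). Note Ksv here is the effective
Stern–Volmer slope of an n = 1.14 isotherm, not an independent constant.

The same analyses are available as library functions
(`albind.fit_stern_volmer`, `albind.fit_double_log`,
`albind.analyze_thermodynamics`, `albind.fit_decay`, `albind.assign_site`,
`albind.helix_percent`, ...) operating on plain dataclasses, and as further
subcommands (`fit-quenching`, `fit-binding`, `thermo`, `fit-lifetime`,
`displace`, `cd`, `sync`, `peaks3d`).

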