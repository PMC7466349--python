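# arsqnmr

Internal-standard ¹H qNMR quantification of **total 5-alkylresorcinols
(ARS)** — the phenolic lipids of wheat and rye bran used as whole-grain
intake biomarkers — in flour, grain and baked products, plus a spin-physics
simulator and the method-validation statistics that establish the assay's
figures of merit.

## The assay

A 330 mg portion of flour (or comminuted product) is extracted for 5 min in
1 mL DMSO-d₆ containing 0.5 mg syringaldehyde as internal standard (IS) and
measured directly at 400 MHz (16 scans, 32 K points over 5263.18 Hz, 10 s
relaxation delay, 3.11 s acquisition). In DMSO-d₆ the three aromatic
protons H-2,4,6 of all ARS homologues collapse into a single singlet at
6.00 ppm with no overlapping matrix signals, so one integral captures the
*total* ARS pool. With the IS aldehyde integral at 9.79 ppm set to 1, the
molar concentration is

```
C [mmol/mg] = (I_ARS / 3) · mmol_IS / M_sample
```

with `mmol_IS = 0.00270` and `M_sample = 330 mg`. Mass concentrations use
the average molecular weight of the dominant C19/C21 homologues,
`MW = (376 + 404)/2 = 390 g/mol`. Detection calls follow S/N ≥ 10
(quantified, LOQ 15 µg ≙ 45 mg/Kg) and S/N ≥ 3 (detected, LOD 10 µg ≙
30 mg/Kg).

Because no spectrometer is required here, the package ships a synthetic
data generator (`spin_sim` / `pipeline`) that emulates the extraction and
acquisition — Lorentzian singlets with T₁ saturation and T₂ decay,
scan-accumulated Gaussian noise, a carbohydrate matrix background and a
single-pool extraction-efficiency model — so every processing and
quantification stage is testable end to end.

## Worked example

```python
from arsqnmr import make_sample, analyze_sample

sample = make_sample("t_monococcum_wholegrain", seed=1)   # 638 mg/Kg preset
result = analyze_sample(sample, seed=1)
print(result.report_row())
```

prints

```
{'sample': 't_monococcum_wholegrain', 'i_ars': 0.6038, 'snr': 148.0,
 'c_mg_per_kg': 642, 'c_mmol_per_kg': 1.65, 'status': 'quantified'}
```

i.e. the simulated whole-grain einkorn flour extract came back at
642 mg/Kg (1.65 mmol/Kg) against its nominal 638 mg/Kg — a 0.6%
single-measurement error at the default noise level — with the ARS singlet
at 148× the noise floor, comfortably above the quantification threshold.
A blank (white-flour) preset returns `status: 'nd'` and prints `ND`.

The same workflow is scriptable from the shell:

```bash
arsqnmr simulate --preset t_monococcum_wholegrain --seed 7 --out run/
arsqnmr process  --input run/t_monococcum_wholegrain_seed7.jdx --output run/spec.jdx
arsqnmr quantify --input run/spec.jdx --output run/report.csv
arsqnmr validate --preset t_monococcum_wholegrain --seed 7 --out run/
arsqnmr report   --input run/report.csv
```

Spectra and FIDs travel as JCAMP-DX 1D text files; reports and manifests as
CSV; every run logs its constants, windows and seeds.

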