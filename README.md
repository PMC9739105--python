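# mtxkit

Quantitative analysis toolkit for characterizing a small disulfide-rich
venom peptide (myotoxin-3, a 45-residue crotamine-family peptide from
rattlesnake venom) as a microtubule-targeting agent. It bundles the four
quantitative workflows such a characterization rests on, each paired
with a seeded synthetic-data generator so every stage is testable
end-to-end without external data:

1. **Peptide mass spectrometry** (`mtxkit.peptides`) — monoisotopic and
   average peptide masses with disulfide oxidation accounting (−2 H per
   bond), MALDI in-source-decay c/z fragment ladders, greedy annotation
   of observed peak lists, inference of residue substitutions from mass
   shifts (the ~24 Da His↔Leu signature), and global-alignment percent
   identity.
2. **Microtubule dynamic instability** (`mtxkit.dynamics`) — segmentation
   of length-vs-time tracks into growth (G) / shortening (S) / pause (P)
   phases and the full statistic set: phase rates and excursion lengths,
   % time per phase, catastrophe (G→S, P→S) and rescue (S→G, S→P)
   frequencies per minute and per µm, and dynamicity
   `(Σ length grown + Σ |length shortened|) / total time`,
   with Welch-tested condition comparisons.
3. **Turbidimetric polymerization** (`mtxkit.polymerization`) — lag time,
   plateau and maximal rate of A350 tubulin-assembly curves.
4. **ITC binding** (`mtxkit.itc`) — the Wiseman one-set-of-sites model
   with perfusion-cell dilution bookkeeping: forward heat prediction,
   blank subtraction, multi-start least-squares estimation of
   (N, K_a, ΔH) and derived ΔG = −RT ln K_a, ΔS = (ΔH − ΔG)/T,
   K_d = 1/K_a.

The synthetic generators (`mtxkit.simulate`) produce dynamic-instability
tracks from an exact Gillespie simulation of a three-state
continuous-time Markov chain, Gompertz turbidity sigmoids, one-site ITC
isotherms (55 µM cell / 2.2 mM syringe / 2 µL injections by default) and
ISD peak lists in the 1000–5000 Da window, all pure functions of
(parameters, seed).

## Worked example

```python
from mtxkit import Peptide, peptide_mass, mass_difference, infer_substitution
from mtxkit.itc import ITCSchedule, fit_one_site
from mtxkit.simulate import MYOTOXIN3_SEQUENCE, ITC_TRUTH, simulate_itc

seq45 = MYOTOXIN3_SEQUENCE                      # YKRCHKKGGH...SVNNA
his45 = Peptide(seq45, n_disulfides=3)
leu45 = Peptide(seq45[:4] + "L" + seq45[5:], n_disulfides=3)

print(f"{peptide_mass(his45, 'average'):.2f}")          # 5168.14
print(f"{mass_difference(his45, leu45, 'average'):.2f}")  # 23.98
print(infer_substitution(23.98, tolerance=0.05, mode="average")[:2])
# [('H', 'I'), ('H', 'L')]   (Leu/Ile are isobaric)

tit = simulate_itc(ITC_TRUTH, ITCSchedule(), noise_sd=2.0, seed=1)
print(fit_one_site(tit).summary())
```

The oxidized average mass of the 45-mer, 5168.14 Da, matches the MALDI
value of the native peptide (5168.3 Da) within 0.2 Da, and the 23.98 Da
mass difference is the His→Leu substitution signature that identifies
the peptide's isoforms. The ITC fit on a 1%-noise synthetic isotherm
recovers the generating truth (N = 2, K_d = 5.3 µM, ΔH = −40 kJ/mol):

```
One-set-of-sites ITC fit
========================================
  N   = 2.00195 +/- 0.0101 sites
  Ka  = 198500 +/- 8.92e+03 1/M
  dH  = -39.6592 +/- 0.267 kJ/mol
  Kd  = 5.038 uM
  dG  = -29.73 kJ/mol
  dS  = -33.87 J/mol/K
  T   = 293.15 K
  chi-square = 23.3709
  c-value    = 21.86
  converged  = True
```

A command-line interface mirrors the library
(`mtxkit simulate|mass|delta|annotate|polym|dynamics|itc|run`); `mtxkit
run config.yaml` executes a YAML-configured multi-stage pipeline and
writes per-stage JSON plus a consolidated report.

```sh
mtxkit simulate --seed 0 --out fixtures   # full synthetic fixture suite
mtxkit dynamics fixtures/tracks.csv       # Table-style dynamics report
mtxkit itc fixtures/itc.csv --blank fixtures/itc_blank.csv
```

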