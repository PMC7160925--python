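# csia-trophic

Trophic position estimation for stable-isotope ecologists working with
compound-specific nitrogen isotope analysis of amino acids (CSIA-AA).

Bulk tissue δ15N cannot be compared across food webs with different
isotopic baselines. CSIA-AA sidesteps the baseline problem by measuring
δ15N of individual amino acids within the same tissue: a *source* amino
acid (phenylalanine, Phe) barely fractionates with trophic transfer and
records the baseline, while a *trophic* amino acid (glutamic
acid/glutamine, Glx) enriches by a trophic discrimination factor (TDF)
per step. The trophic position (TP) then follows from the Glx−Phe
difference alone.

The package implements:

- **TP estimators** —
  classic: TP = (δ15N_Glx − δ15N_Phe − β)/7.6 + 1;
  tissue-aware multi-TDF: TP = 2 + (δ15N_Glx − δ15N_Phe − TDF_tissue − β)/6.2
  with β = 3.4‰ (producer Glx−Phe offset), TDF_tissue = 3.5‰ for
  feathers and egg membranes, 4.0‰ for red blood cells; and a
  multi-amino-acid variant averaging per-AA estimates (Glx, Ala, Leu,
  Ile, Pro, Asp) with user-supplied per-AA constants.
- **Paired-tissue TDF calibration** — grid search for the tissue-B TDF
  that minimises the mean absolute TP difference between tissues grown
  over the same period (e.g. chick feathers vs chick red blood cells),
  plus the closed-form solution.
- **Habitat classification** — polar vs temperate foraging/moulting
  grounds from bulk δ13C (polar strictly below −21‰).
- **Summary-statistic comparison layer** — Welch t-tests, one-way ANOVA
  and Tukey–Kramer compact letter displays computed from per-group
  (n, mean, SD), exactly equal to their raw-data counterparts; Levene
  (Brown–Forsythe) and Shapiro–Wilk diagnostics; duplicate-measurement
  repeatability as a one-way intraclass correlation.
- **Synthetic data** — per-sample generators parameterised by the group
  summaries of a published Falkland Islands seabird community dataset
  (three penguins, two petrels), so the full pipeline runs with no
  downloads.
- **CLI** — `csia-trophic simulate | tp | classify | compare | run`.

## Worked example

```python
from csia_trophic import AAProfile, tp_multi_tdf

# Magellanic penguin red blood cells, breeding season group means (‰)
profile = AAProfile({"Glx": 26.2, "Phe": 6.9})
result = tp_multi_tdf(profile, "red_blood_cells")
print(round(result.tp, 2), result.constants_used)
```

prints

```
3.92 {'beta': 3.4, 'tdf_glx_phe': 6.2, 'tissue_tdf': 4.0}
```

i.e. a trophic position of 3.9 — a piscivore feeding roughly two steps
above herbivorous zooplankton — computed as 2 + (26.2 − 6.9 − 4.0 − 3.4)/6.2.

End to end from the command line:

```sh
csia-trophic simulate --table table3 --seed 42 --out samples.csv
csia-trophic tp samples.csv --group-by species
```

which emits a per-species table of n, mean ± SD for δ13C, δ15N, TP, Glx
and Phe (e.g. Gentoo penguin feathers around TP 2.9, Wilson's
storm-petrel around 4.0).

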