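# murkit

Toolkit for the computational side of chloroplast peptidoglycan precursor
studies: identifying UDP-linked muropeptide precursors in negative-ion TOF
peak lists, and characterizing the Mur-ligase enzymology (MurE in
particular) that builds them.

Mosses and other early-diverging plants retain a bacterial-type
peptidoglycan wall around their chloroplasts. Its cytoplasmic precursors
form a ladder of UDP-linked intermediates — UDP-GlcNAc through
UDP-MurNAc-pentapeptide — whose stem peptide carries either meso-DAP
(Gram-negative-type, including cyanobacteria and chloroplasts) or L-Lys
(Gram-positive-type) at position 3. `murkit` answers two questions about
data from such studies:

1. **Which precursors are present in a mass-spectrometry peak list?**
   Each precursor's neutral composition is assembled from free-molecule
   building-block formulas with one water lost per bond; negative-mode ions
   are enumerated as

   `m/z = (M − z·m_H + k·(m_Na − m_H)) / z`

   for charge z = 1–3 and k = 0–3 sodium-for-hydrogen exchanges, and
   observed peaks are assigned to the nearest ion within a ppm tolerance
   (default 30 ppm). A precursor is identified when it has ≥ `min_ions`
   matches including at least one sodium-free deprotonated ion — adducts
   corroborate, they never establish.

2. **What are the kinetics of the ligase that makes them?** Initial rates
   from the coupled ADP-release assay (v₀ = −(dA₃₄₀/dt)/(ε·l)/[E], in
   mol ADP·mol ligase⁻¹·s⁻¹), nonlinear fits of v = V·S/(K_M + S)
   (Michaelis–Menten) and v = V·S/(K_M + S·(1 + S/K_i)) (substrate
   inhibition) with R²/AICc model comparison, diprotic pH-bell fits
   v(pH) = v_opt/(1 + 10^(pK₁−pH) + 10^(pH−pK₂)), and amino-acid
   specificity statistics (group means, 95% CIs, unpaired two-tailed
   t-tests).

Also included: DAP-specificity motif scanning (DNPR and variants) with
transit-peptide trimming and a Needleman–Wunsch percent identity, seeded
synthetic-data generators for every input type, and a CLI.

## Worked example

The precursor ladder, from building-block compositions alone:

```
$ murkit ladder
identifier	formula	monoisotopic_mass	pathway_index
UDP-GlcNAc	C17H27N3O17P2	607.0816	0
UDP-MurNAc-Ala	C23H36N4O20P2	750.1398	1
UDP-MurNAc-Ala-Glu	C28H43N5O23P2	879.1824	2
UDP-MurNAc-tripeptide-DAP	C35H55N7O26P2	1051.2672	3
UDP-MurNAc-pentapeptide-DAP	C41H65N9O28P2	1193.3414	4
```

Each mass M is the neutral monoisotopic mass in Da; e.g. the deprotonated
UDP-GlcNAc ion appears at (607.0816 − 1.0078)/1 = 606.0737.

End-to-end identification of the bundled observed peak table (transcribed
from the published negative-ion TOF data, 50 observed values):

```
$ murkit reproduce-table1 | tail -8
max |computed - printed| expected m/z: 0.0004 Da
identified intermediates (5):
  UDP-GlcNAc
  UDP-MurNAc-Ala
  UDP-MurNAc-Ala-Glu
  UDP-MurNAc-tripeptide-DAP
  UDP-MurNAc-pentapeptide-DAP
```

All five detected intermediates are recovered; no peak is assigned to a
Lys-containing species, mirroring the in-vivo DAP specificity.

Kinetics, on synthetic substrate-inhibition data (truth: Vmax = 2 ADP/s,
K_M = 50 µM, K_i = 500 µM, 5% noise, 3 replicates):

```python
import numpy as np
from murkit import *

rs, truth = simulate_rate_series("SI", dict(vmax=2.0, km=50.0, ki=500.0),
                                 np.geomspace(5, 1000, 10), sigma=0.05,
                                 replicates=3, seed=42)
mm = fit_michaelis_menten(rs)
si = fit_substrate_inhibition(rs)
```

prints, via the obvious f-strings:

```
MM: Vmax=1.057 ADP/s  KM=13.4 uM  R2=0.6972
SI: Vmax=1.800 ADP/s  KM=40.9 uM  Ki=624 uM  R2=0.9527
selected by R2: SI; AICc advisory: SI
kcat=1.800 s^-1  kcat/KM=0.04398 uM^-1 s^-1 (apparent)
```

The substrate-inhibition model is selected (R² 0.95 vs 0.70) and the
apparent catalytic efficiency k_cat/K_M ≈ 0.044 µM⁻¹s⁻¹ is within 10% of
the generating truth (0.04). Fitters are scikit-learn estimators
(`MichaelisMentenRegressor`, `SubstrateInhibitionRegressor`,
`PHBellRegressor`) and compose with sklearn tooling; all constants are
"apparent" (co-substrates fixed).

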