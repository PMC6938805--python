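# sprayrisk

Time-dependent soil exposure and earthworm mixture risk of pesticide spray
series.

In conventional agriculture, pesticides are applied as a *spray series*: a
chronological sequence of applications — sometimes several products on the
same day (tank mixtures), sometimes weeks apart — within one or more growing
seasons. Because each active ingredient degrades at its own pace, residues
from earlier sprays overlap with fresh deposits, and soil organisms such as
earthworms are continuously exposed to a changing pesticide *mixture*.
`sprayrisk` simulates that mixture day by day and reports when and for how
long the combined risk exceeds a regulatory threshold. It is aimed at
ecotoxicologists and regulators who want a transparent, scriptable
screening-level assessment.

## The model

**Initial exposure.** Each application deposits an initial soil
concentration (PIEC, predicted initial environmental concentration)

```
PIEC [mg/kg] = AR · (1 − CIF/100) / (100 · d · p)
```

with AR the application rate [g a.i./ha], CIF the crop interception factor
[%] looked up from the crop's BBCH development stage, d the mixing depth
[cm] and p the dry-soil bulk density [g/cm³] (default 1.5). The mixing depth
is either user-fixed or, with the token `mix` (German registration
convention), 1 cm for strongly sorbing substances (Kfoc > 500 L/kg) and
2.5 cm otherwise — the shallow depth gives 2.5-fold higher initial
concentrations.

**Degradation.** Concentrations decay by single first-order kinetics,
k = ln 2 / DT50s, with the half-life Arrhenius-corrected to the monthly mean
temperature:

```
DT50s = DT50soil · F · exp( Ea/R · (1/T − 1/Ts) )
```

(Ea = 54 000 J/mol, R = 8.314 J/(mol·K), Ts = 20 °C reference by default, F a
per-application degradation factor). Cold months slow degradation; the daily
series is never rounded or floored, so the exponential tail is preserved.

**Mixture risk.** Each simulated day is treated as one mixture under
concentration addition. Per component, ETR = PEC / endpoint (earthworm LC50
for acute, reproduction NOEC for chronic risk) and TER is its reciprocal.
The mixture indices are

```
ETRmix = Σᵢ ETRᵢ          TERmix = ( Σᵢ 1/TERᵢ )⁻¹  =  1 / ETRmix
```

Days with TERmix strictly below a threshold (defaults: acute 10, chronic 5,
both configurable) are collected into exceedance intervals.

## Worked example

Generate the bundled six-application apple scenario (four sprays of a
fast-degrading dithiocarbamate fungicide, two of a slow anilinopyrimidine)
and run it:

```python
from sprayrisk.fixtures import make_reference_apple_scenario
from sprayrisk.data_tables import write_compoundtab, write_croptab, write_maintab

scenario, compounds, croptab = make_reference_apple_scenario()
write_compoundtab(compounds, "demo/compoundtab.csv")
write_croptab(croptab, "demo/croptab.csv")
write_maintab(scenario, "demo/maintab.csv")
```

```
$ sprayrisk --maintab demo/maintab.csv --compoundtab demo/compoundtab.csv \
            --croptab demo/croptab.csv --outdir demo/out
[acute] no exceedance of the TER threshold 10.0
[chronic] TERmix falls below 5.0 from day 91 (4 day(s) below)
outputs written to demo/out
```

The chronic mixture risk dips below the threshold on the four days the fast
fungicide is sprayed (it is gone within days, so the risk recovers each
time), while the acute threshold is never crossed. `demo/out/pec_table.csv`
holds one column per application in chronological order plus the cumulative
sum — around the first spray day:

```
days,Mancozeb,Mancozeb,Mancozeb,Pyrimethanil,Mancozeb,Pyrimethanil,cumulative
90,0.0,0.0,0.0,0.0,0.0,0.0,0.0
91,5.333333333333333,0.0,0.0,0.0,0.0,0.0,5.333333333333333
92,0.019523970012202477,0.0,0.0,0.0,0.0,0.0,0.019523970012202477
93,7.147226344450904e-05,0.0,0.0,0.0,0.0,0.0,7.147226344450904e-05
```

Day 91 carries the full initial concentration (2 kg a.i./ha at 60 %
interception into 1 cm of soil → 5.33 mg/kg); decay starts the following
day. Figures land in four folders — `plots_PEC` and `plots_ETR` (per-event
courses), `plots_All` (all events plus the ETRmix line) and `plots_TER`
(TERmix against the dotted threshold on a log axis) — and
`exceedance_report.txt` lists the threshold, the first exceedance day and
every below-threshold interval.

## Input tables

* `compoundtab.csv` — columns `compound_id` (row number minus one),
  `compound_name`, `cas_nr`, `chemical_class`, `chemical_use`,
  `degt50_soil` [d], `lc50_earthworm`, `noec_earthworm` [mg a.i./kg dw],
  `kfoc` [L/kg]. Blank property cells are imputed from the class (then use)
  mean of the other substances.
* `croptab.csv` — `crop_id`, `crop_name`, `bbch_min`, `bbch_max`,
  `interception_pct`; non-overlapping BBCH ranges per crop.
* `maintab.csv` — variables as rows, one value column per application for
  `compound_name`, `Com_ID`, `application_month`, `ApplicationRate_kgai_ha`
  [kg a.i./ha], `application_day` (julian), `BBCH`, `degradation_factor`,
  `mixing_depth_m` (metres or `mix`); scenario-level rows `description`,
  `numb_applications`, `crop_id`, `days_of_year` and `TEMP_JAN` … `TEMP_DEC`
  [°C] (one column per simulated year, or one recycled set). Every cell of
  an application column must be filled.

All dialect options (separator, decimal mark) are configurable via CLI
flags; `sprayrisk --help` lists everything, `sprayrisk --list-checks` prints
the model's invariant checklist.

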