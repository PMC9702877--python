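# fragkin

Cell-free DNA fragmentomics, qPCR integrity indices, and degradation
kinetics for NET-derived circulating DNA.

Circulating cell-free DNA (cirDNA) is detected in blood mostly as
mononucleosome-associated fragments (~167 bp). Neutrophil extracellular
traps (NETs) — webs of decondensed chromatin expelled by activated
neutrophils, decorated with neutrophil elastase (NE) and
myeloperoxidase (MPO) — release high-molecular-weight chromatin that
serum nucleases and the NET enzymes themselves catabolize down to
mononucleosomes. `fragkin` is a library for analyzing this process: it
profiles fragment sizes at 1 bp resolution from aligned read pairs,
quantifies DNA by qPCR standard curves with paired short/long amplicon
integrity indices, estimates degradation rates in blood fluids, runs
cohort-level biomarker statistics, and ships synthetic generators for
every input it consumes. It is written for researchers working on
cfDNA biology, liquid biopsy, and NET-associated inflammatory disease.

## Core quantities

**Fragment-size profile.** Insert sizes are the absolute signed
template lengths (TLEN) of properly paired reads, one per pair, after
removing supplementary/secondary alignments, PCR duplicates, MapQ < 20
records, and lengths outside (0, 1000] bp. The 1 bp histogram exposes
the nucleosomal structure: mono-N mode at 167 bp, di-N near 320–365 bp,
tri-N near 560 bp, and below ~167 bp a ladder of subpeaks with ~10 bp
periodicity (nuclease nicking at exposed minor-groove sites on the
nucleosome). Mono/di/tri/long fractions are masses in configurable
intervals of the 20–1000 bp window.

**qPCR quantification and integrity.** Concentration follows from a
serial-dilution standard curve `Cq = b + m·log10(C)` with efficiency
`10^(−1/m) − 1`. Paired amplicons at one locus (73/246 bp on *SRY*,
67/320 bp on *KRAS*) give the DNA integrity index `DII = C_long /
C_short` — near 1 for intact DNA, 0 for purely mononucleosomal
fragments, since a 246 bp amplicon cannot sit inside a 167 bp fragment.
The amplifiable fraction of a fragment population for an A bp amplicon
is `Σ w_i max(0, L_i − A + 1) / Σ w_i L_i`. `MNR = C_mt / C_nuclear`
compares mitochondrial and nuclear cfDNA.

**Degradation kinetics.** Overall rate over an interval is
`(C(t0) − C(t1)) / (t1 − t0)` in ng DNA/mL/min. Because EDTA plasma
inhibits nucleases, subtraction attributes degradation: nuclease rate =
control serum − control plasma; NE/MPO rate = supplemented serum −
control serum. Single- and biexponential decay fits support parameter
recovery. The synthetic degradation model is a four-compartment linear
cascade (HMW → tri-N → di-N → mono-N → lost) integrated by matrix
exponential, with per-condition rate multipliers.

## Worked example

`examples/05_net_degradation.py` simulates the serum catabolism of
NET-derived DNA with the calibrated default cascade:

```
chrY DNA lost (qPCR view):
  after 10 min   28.0%
  after 30 min   48.0%
  after 24 h     71.0%
24 h fragment fractions (20-1000 bp, sWGS view): mono 80.1%, di 14.8%, tri 5.1%
```

Fast loss of HMW/oligonucleosomal DNA followed by slow decay of the
nucleosome-shielded remainder: by 24 h, 71% of the spiked chrY DNA is
gone and ~80% of the surviving 20–1000 bp fragments are
mononucleosomal. `examples/02_degradation_rates.py` computes, from
endpoint concentrations of an enzyme-supplementation experiment
(500 ng/mL input; control serum 207/124 ng/mL at 2 h/8 h):

```
fold decrease vs control serum at 8 h:
  NE       5.4-fold
  MPO      8-fold
  NE+MPO   25-fold
NE at 2 h: 3-fold
NE+MPO degraded 99% of input at 8 h
overall serum rate (0-2 h):   2.44 ng/mL/min
nuclease-attributed rate:     2.23 ng/mL/min
NE-attributed extra rate:     1.19 ng/mL/min
```

The other examples cover size profiling from SAM records (01), standard
curves and DII (03), NET production kinetics with marker co-release
(04), and cohort statistics (06).

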