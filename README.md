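# karsim

A deterministic, discrete-time simulator of the **kiss-and-run (KAR)
model of intra-Golgi transport** — the idea that secretory cargo and
Golgi-resident enzymes are concentrated not by vesicles or by cisternal
progression but by repeated transient fusion/fission ("kiss-and-run")
events between adjacent compartments of the secretory pathway.

It is written for cell biologists and modelers who want to explore how far
a minimal fusion/fission rule goes in explaining Golgi concentration
gradients, and to compare its kinetic signature against caricatures of the
competing diffusion and compartment-progression models.

## The model

The pathway is an ordered chain of compartments
(ER, IC, *cis*, med1…med4, TGN, PGC for soluble cargo; ER, *cis*,
med1…med5, TGN, PGC for resident enzymes), each holding an amount of
protein in arbitrary *conditional units*. Time advances in rounds. Two
pairings of adjacent compartments alternate —
phase 1: ER–IC, *cis*–med1, med2–med3, med4–TGN;
phase 2: IC–*cis*, med1–med2, med3–med4, TGN–PGC —
so that every junction of the chain fuses every other round.

When a pair fuses, an inter-compartment ionic gradient drives uneven
repartitioning of the pooled content *T*: the depleted member keeps
*T*/(1+r) and the enriched member r·*T*/(1+r), with ratio **r = 2**. In
integer mode the depleted side is rounded to the nearest integer and the
enriched side takes the remainder, so each pair's total is conserved
exactly. Three boundary rules complete the model:

* **Source clamp** — the ER synthesizes protein continuously: it is held
  at 10 units, and its fusion partner is set to r × 10 = 20.
* **Direction profile** — normally the distal member of a pair is
  enriched (anterograde). For resident enzymes the pump gradient inverts
  distal to med4, so the pairs med4–med5, med5–TGN and TGN–PGC enrich
  their *proximal* member; the enzyme peak therefore parks at med4.
* **Departure** — once the terminal post-Golgi compartment (PGC) exceeds
  5-fold the 10-unit baseline, its content departs and is logged.

The dynamics are fully deterministic. The package ships the two canonical
worked scenarios as both ready-made configs and printed reference tables
(`table1`: soluble cargo, `table2`: glycosylation enzymes), reproduces the
reference matrices cell-exactly over a verified range, and catalogues the
few printed cells that violate pairwise mass conservation as errata.

Beyond the simulator, `karsim.kinetics` provides fold-enrichment profiles,
peak localization, departure bookkeeping, a first-order
(A·e<sup>−kt</sup>) exit fit, and two baseline models: a *diffusion*
caricature (permanently connected compartments fully equilibrate each
round; washout is exactly geometric) and a *conveyor* caricature
(contents march one compartment distally each round; a pulse exits as a
single spike).

## Worked example

Run the enzyme scenario for 11 rounds and check it against the shipped
reference table:

```text
$ karsim table table2 --rounds 11 --out demo
table2: rounds 1-11, 1 mismatch(es)
  round 2, cis: simulated 9, printed 7
all mismatches are annotated errata of the printed table
```

The one mismatch is a known erratum in the reference matrix: at round 2
the *cis*–med1 pair pools 20 + 7 = 27 units, which the 1:2 rule can only
split 9/18; the printed 7/18 does not conserve the pair. Every other cell
through round 11 matches, including the bold med4 peak of 40 units
(4.0-fold enrichment).

Run the cargo scenario from its YAML config:

```text
$ karsim run --config src/karsim/data/table1.yaml --rounds 18 --out demo1
wrote 19 rows to demo1/trajectory.tsv
$ head -4 demo1/trajectory.tsv
round	ER	IC	cis	med1	med2	med3	med4	TGN	PGC
0	10	0	0	0	0	0	0	0	0
1	10	20	0	0	0	0	0	0	0
2	10	7	13	0	0	0	0	0	0
```

Round 1 shows the ER–IC fusion doubling the cargo to 20 units (2-fold);
round 2 splits those 20 units 7/13 into *cis*. A concentration wave then
walks distally; the PGC reaches 19 units by round 18 and first departs
(>50 units) at round 32.

Compare the three transport models:

```text
$ karsim compare --out cmp.csv
wrote 3 model summaries to cmp.csv
```

The CSV reports, per model, the exit half-time, the first-order fit rate
and R², and the peak compartment and fold. The diffusion baseline's
washout is exactly exponential (R² = 1.0), the conveyor's single-spike
exit fits an exponential poorly (R² ≈ 0.79), and the kiss-and-run run
concentrates cargo 4.4-fold in the PGC.

As a library:

```python
import karsim

traj = karsim.run(karsim.build_table2_config(), n_rounds=11)
print(traj.cell(11, "med4"))                      # 40.0
print(karsim.peak_compartment(traj.state(11)))    # med4
```

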