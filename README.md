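# polexo

Kinetic-partitioning analysis for proofreading DNA polymerases: mass-action
ODE simulation of the branched polymerase/exonuclease binding mechanism,
global fitting of single-turnover quench-flow time courses, integrated flux
partitioning, van't Hoff thermodynamics, and a mismatch-fate simulation that
quantifies the net contribution of proofreading to replication fidelity.

## What is in the box

| module | purpose |
| --- | --- |
| `polexo.models` | Domain types (`Species`, `Reaction`, `KineticScheme`, parameter sets) and the three mechanism builders: branched excision, pre-equilibrated two-state extension, and the chained excision-vs-extension fate scheme. |
| `polexo.engine` | Stiff ODE integration (LSODA, analytic Jacobian, rtol 1e-8/atol 1e-12) with a protocol layer for mixing and relax-to-equilibrium phases, observables, a seeded Gillespie oracle, and delimited-text `TimeCourse` I/O. |
| `polexo.flux` | Time-integrated one-way/net flux between competing branches and the binding / internal-transfer partitions. |
| `polexo.fitting` | Multi-start least-squares fitting by simulation in log-parameter space (bounded TRF + LM polish), locked/floated parameters, SVD-based standard errors with honest not-determined reporting, and the kcat/Km upper-limit bound. |
| `polexo.analysis` | Pol-site occupancy, reverse transfer rate, two-point van't Hoff ΔG°/ΔH°, fold changes, and the mismatch-fate report computed by two independent routes (ODE absorption and embedded jump-chain algebra) that must agree. |
| `polexo.synth` | The transcribed fitted-constant catalogue (four experiment families plus extension kinetics), seeded noise model, and synthetic excision/extension dataset generators. |
| `polexo.cli` | `polexo` command-line workbench. |

Units throughout: concentrations in µM, times in seconds, unimolecular rate
constants in s⁻¹, bimolecular in µM⁻¹s⁻¹.

## CLI

```bash
polexo simulate --table excision_20C --row 1 --out sim.tsv
polexo generate --table excision_20C --row 1 --replicates 3 --seed 7 --out data.tsv
polexo fit --data data.tsv --table excision_20C --row 1 --out fit.json
polexo flux --table excision_20C --row 4 --out flux.json
polexo fate --out fate.json
polexo thermo --k-low 0.033 --t-low 277.15 --k-high 0.061 --t-high 293.15 --out thermo.json
polexo report --out report.json
polexo limit --out limit.json
```

Fixture tables: `excision_4C`, `excision_20C` (rows `0`–`5`, number of
terminal mismatches), `buried_excision_20C` (rows `n-0`–`n-10`, buried
mismatch position), `buried_extension_20C` (extension kinetics), and
`mismatch_extension` (steady-state extension constants / upper limits used
by the fate analysis). Every output embeds its resolved configuration and
the package version. Exit codes: 0 success, 2 usage error, 3 numerical
failure.

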