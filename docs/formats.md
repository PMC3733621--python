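# File formats

All tables are UTF-8, tab-separated, with a mandatory header row.

## Network TSV

One file, two sections introduced by comment lines:

```
# metabolites
id	role	name
GLCx	boundary	extracellular glucose
G6P	internal	glucose 6-phosphate
HISBIOx	biomass-sink	histidine drain sink
# reactions
id	equation	gamma	gpr	class	name
glk	GLCx + ATP -> G6P	1	Y001 or Y002	mass_action_irreversible	glucokinase
pgi	G6P <-> F6P	1	Y003	mass_action_reversible
his_syn1	R5P + METTHF + 2 ATP -> IAP	3	(Y010 and Y011) or Y012	mass_action_irreversible
his_drain	HIS + ATP -> HISBIOx	1		amino_acid_drain
```

- `role` is one of `internal`, `boundary`, `biomass-sink`; only internal
  metabolites enter steady-state balances.
- `equation` uses `->` (irreversible) or `<->` (reversible); coefficients
  precede metabolite ids (`2 ATP`).
- `gamma` is the number of lumped irreversible steps (1 for individual
  reactions; values > 1 mark the reaction as lumped).
- `gpr` is a boolean gene association over `and`/`or` with parentheses;
  empty means no association.
- `class` is one of `mass_action_irreversible`, `mass_action_reversible`,
  `amino_acid_drain`, `generic_drain`, `fixed_exchange`; empty defaults by
  reversibility.
- Unknown columns are ignored with a logged warning.

## Network JSON

The same record structure as the TSV, as
`{"metabolites": [{id, role, name}...], "reactions": [{id, equation,
gamma, gpr, class, name}...]}`.

## SBML

Level 3 Version 1. Species carry the role in a `gemkin:meta` annotation
and `boundaryCondition` mirrors non-internal roles; reactions carry
`gamma`, `kinetic_class`, `lumped`, the optional `reference_flux` and the
GPR string in a `gemkin:kinetics` annotation, plus the rate law as MathML.
Re-import recovers stoichiometry, reversibility and the annotations
exactly.

## Data tables

- flux TSV: `reaction_id <tab> flux`
- exchange-measurement TSV: `reaction_id <tab> rate` (optional `sd`)
- expression ratio TSV: `gene_id <tab> value`
- observed concentration TSV: `metabolite <tab> ratio`
- raw intensity table: genes as rows, one column per array named
  `<condition>_<replicate>`

## YAML run configuration

```yaml
paths:
  network: network.tsv        # or .json / .xml (SBML)
  fluxes: fluxes.tsv          # or exchanges: measured rates
  expression: ratios.tsv      # optional
  output: out/
parameters:
  alpha: 0.1
  beta: 30.0
  lambda: 1.0
  inhibition: {his_syn1_b: 0.487}
  woa_uptake: 0.0
  atp_per_woa: 2.0
solver:
  tol_residual: 1.0e-9
chemostat:
  dilution_rate: 0.1
  glucose_uptake_reaction: glk
  glucose_species: GLCx
  biomass_floor: 1.0e-3
seed: 1
```

Unknown keys are rejected.
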