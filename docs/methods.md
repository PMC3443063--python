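# Methods

## The projection model

A genome-scale metabolic model is treated as a tuple of compartments,
metabolites, reactions (signed stoichiometry, flux bounds in
mmol·gDW⁻¹·h⁻¹), gene associations, and a biomass objective. Projection
assumes that a reaction present in a curated *scaffold* species is present in
the *target* species exactly when its gene requirements are conserved; all
structural context (compartments, metabolite identities, spontaneous and
non-enzymatic transport reactions, exchanges) is inherited from the scaffold
unchanged. This is a deliberately conservative model of metabolic evolution:
it can only remove enzymatic capabilities (gene loss) or re-label them
(orthology), never invent target-specific biochemistry — species-specific
reactions enter through an explicit insertion operation backed by manual
curation or EC-code evidence.

### GPR semantics and rewriting

A Gene-Protein-Reaction association is a boolean formula over gene
identifiers (AND = complex subunits, OR = isozymes). The canonical form used
everywhere is the list of **minimal gene sets**: the inclusion-minimal gene
combinations each sufficient to carry the reaction. Although this corresponds
to a disjunctive normal form, it is exactly the "list of alternative ways to
encode the same reaction" a curator reads, and it makes conservation testable:
a reaction is conserved iff at least one minimal gene set maps completely.

Rewriting substitutes each scaffold leaf by the OR of its candidate target
genes. An unmapped leaf is dropped from an OR (another isozyme can still
carry the reaction) but poisons an AND (the complex cannot assemble). The
result is re-normalized (duplicates merged, absorption applied), so
collapses such as two scaffold paralogs hitting one target gene fall out
automatically. Rewrites are classified per leaf — one-to-one (M3),
scaffold-side collapse onto a shared target (M4 pair / M5 family),
target-side expansion (M6 pair / M7 family), loss (M1 when nothing
survives) — and the reaction's label is the unique non-M3 case when exactly
one exists, because a formula combining a plain substitution with, say, one
target-side duplication is conventionally labelled by the interesting event.
Two distinct non-trivial cases, or a partial loss inside a surviving OR,
give `mixed`. Gains (M2) are produced only by species-specific insertion.

### Consensus orthology

No single orthology method handles duplication, family expansion and fusion
equally well, so candidate maps from several methods are pooled. Per
scaffold gene, target genes proposed together (same method, same
paralog-group label) are linked, and connected components of those links
across methods form candidate groups; each group scores one vote per method
proposing any of its members. Two modes: `all` keeps every group with ≥
`min_votes` (default 1) votes; `top` (default, for divergent predictions)
keeps only the top-voted group(s). A tie at the top keeps all tied groups and
unions them at rewrite time — conservative in the sense that it retains
reactions rather than dropping them — and the tie is logged.

### Biomass adjustment

The scaffold biomass function is reused with one principled edit: the DNA
precursor term is re-balanced for the target genome. dGTP and dCTP
coefficients are each set proportional to gc/2 and dATP/dTTP to (1−gc)/2,
scaled so the summed precursor mass equals either the scaffold's original
summed mass (default) or a user-supplied DNA mass fraction (g·gDW⁻¹), e.g.
derived from genome length. Precursor "molar masses" default to 1 g·mmol⁻¹ —
appropriate for the topological fixtures; pass real molar masses for real
models. No published formula exists for this adjustment; proportional-to-GC
with mass conservation is this package's design choice. All other biomass
coefficients pass through untouched.

## Simulation and validation

FBA maximizes the biomass flux subject to steady-state mass balance
S·v = 0 (rows: non-boundary metabolites) and the flux bounds, solved with
scipy's HiGHS interface. Every optimal solution is checked against mass
balance and bounds at 1e-6 before being returned; only the objective value
is contract-guaranteed, since flux vectors at degenerate optima are
solver-dependent. Media are applied in a fixed order — close all exchange
uptakes, open the configurable non-carbon base nutrients, apply the medium's
own bounds last — so a medium can override the base. Defaults follow COBRA
conventions where the underlying studies leave them unstated: bound
magnitude 1000, carbon uptake cap 10 mmol·gDW⁻¹·h⁻¹, absolute growth
threshold 1e-6 h⁻¹ with a strict inequality (a relative-to-wild-type
threshold is available). Knockouts zero the bounds of every reaction whose
GPR evaluates false with the deleted genes absent; GPR-less reactions are
never touched. Experimental OD curves are binarized at one third of the mean
OD across the cohort measured together.

Validation runs each experiment record (medium, knockout set, observed
growth) through apply-media → knockout → FBA → binarize and scores the
(observed, predicted) pairs as a confusion matrix. Observed growth is the
positive class. The summary statistic is the geometric mean of sensitivity
and specificity, robust to class imbalance; when a class is absent the
defined rate is reported alone and flagged `partial`. Reports print accuracy
to two decimals; JSON keeps full precision.

## Gap analysis

Dead ends are structural (a non-boundary metabolite with only producers or
only consumers, reversibility respected). Blocked reactions have zero flux
range under the medium by flux variability, with 1e-9 as numerical zero.
A biomass precursor is disconnected when a temporary demand on it cannot
carry flux. Candidate fixes are ECs annotated in the target genome but
absent from the draft, ranked: gap-closing templates first, known
stoichiometry next, template-less ECs last. No optimization-based (MILP)
gap-filling is attempted — candidates feed manual curation.

## The synthetic study

The fixture generator emulates the full input suite at toy scale:
`n_linear_pathways` (default 6) alternative carbon sources, each a linear
chain (`pathway_length` = 5) converging on a central carbon metabolite
consumed by biomass, so any single carbon source supports growth and a chain
knockout is lethal exactly on its own medium; isozyme (OR, 8 reactions) and
complex (AND, 6) associations; chains routed through a third compartment to
create transports; DNA precursors synthesized from the nitrogen source; and
8 dispensable secreted side branches. Evolutionary events are planted per
reaction from `event_mix` (defaults: 42% one-to-one, 10% each scaffold-side
collapse type, 15% each target-side expansion type, 8% loss), with two
deliberate biases: losses are planted only on dispensable side branches so
the projected target stays functional (a loss on the sole biomass route
would flatten every growth prediction), and every event with positive
probability is planted at least once on a compatible reaction so recovery
tests see all cases. Ortholog maps are per-method views of the planted
truth (identical at the default zero noise; with noise a method may miss a
gene or add a spurious candidate), with multi-target families sharing a
paralog-group label.

Experiment tables carry 152 rows of which 98 are observed — 55 with
ground-truth growth and 43 without, the composition implied by the
reference validation's printed counts — and observations are flipped for 16
growth rows and 18 no-growth rows, so scoring the uncorrupted model against
the table reproduces the published confusion-matrix shape (39/25/16/18,
geometric mean 0.65) by construction. Ground truth is *computed by
simulation*, never asserted: each candidate condition is run through the
same media/knockout/FBA pipeline being tested.

Determinism: each generator stage draws from its own stream seeded by
(user seed, stage tag), so adding stages never perturbs earlier output;
identical specs produce byte-identical SBML and tables.

What the fixtures do **not** emulate: real stoichiometric mass balance with
cofactors, thermodynamic constraints, realistic network redundancy, or any
actual yeast biochemistry. Passing the recovery tests shows the *machinery*
(voting, rewriting, conservation calls, scoring) is correct under known
ground truth; it says nothing about the biological accuracy of any real
projection, which still depends on ortholog-map quality and curation.

## Numerical and formatting choices

- LP: HiGHS via scipy; mass-balance/bound verification at 1e-6; FVA zero at
  1e-9; an infeasible medium reports all reactions blocked with a flag
  rather than raising.
- Census percentages are one-decimal machine values; the human report drops
  the decimal for whole percentages ≥ 5 (prints `7%`, not `7.0%`).
- Minimal gene sets and group lists are ordered lexicographically;
  consensus ties are kept and logged; the SBML writer emits elements in
  model insertion order, giving reproducible files.
- Degenerate inputs: empty GPR strings and sentinel values (`-`, `N/A`)
  mean "no association"; an unparseable GPR is a warning plus diagnostic,
  never a parse failure for the whole model; a model without a biomass
  reaction cannot be projected (functionality would be undefined).

## Known limitations

- Reaction categories (exchange/transport/enzymatic) are inferred
  structurally when not annotated; the transport test relies on recognizing
  the same species in two compartments via name or id-suffix convention.
- Only the DNA term of biomass is adjusted; other composition terms pass
  through from the scaffold.
- The `any-mapped-leaf` conservation rule keeps a reaction on partial
  evidence but cannot write a sound association for a poisoned AND; such
  reactions keep no GPR and are flagged.
- Problem sizes: the test suite and the acceptance run use the default toy
  study (86-reaction scaffold, 152 experiments), which exercises every code
  path while solving a few hundred small LPs.
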