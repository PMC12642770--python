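# Methods

## Model and procedure

`gifms` treats MS/MS spectrum simulation as a two-step structured
reasoning task delegated to a chat-completion backend, with all chemistry
validation and mass arithmetic kept offline.

**Step 1 — fragment generation.** The backend receives a system prompt
naming the domain and the fragmentation task, and a user prompt carrying
the task tag, the query molecule and the experiment settings as JSON
payloads, with instructions to return fragment strings in order of
descending intensity. Each response is filtered with two checks: the
string must decode to a valid molecule (RDKit), and the decoded
heavy-atom graph must be subgraph-isomorphic to the parent's. The
filtered list plus the invalid count are embedded in a refinement prompt
and the cycle repeats: 1 initial query + `n_fragment_refinements`
(default 5) refinement rounds. The filtered output of the final round,
deduplicated by 2-D identity with the earlier (higher predicted
intensity) occurrence winning, is the final ranked fragment list.

**Offline m/z.** Each fragment's peak position is
(monoisotopic mass + adduct shift) / |charge|. Monoisotopic masses come
from RDKit's periodic table (most abundant isotope); charge carriers use
the proton mass (1.00727646688 Da), not the hydrogen-atom mass. The
shipped adduct table covers [M+H]+, [M+Na]+, [M+NH4]+, [M−H]− and
[M+H−H2O]+ and is extensible at run time.

**Step 2 — intensity prediction.** The backend receives the fragment/m-z
list in generation order and must return an integer level in
[1, scale_max] (default 10) per m/z. Cleaning removes entries whose m/z
was not queried (compared at the printed 4-decimal precision — backends
echo rounded text), duplicates (first occurrence wins), and invalid
levels. Cleaned levels are merged onto the fragment list, one refinement
query is issued (`n_intensity_refinements` default 1), and the final
levels map to relative intensities level/scale_max, renormalized to base
peak 1.0.

**Temperature schedule.** Fragment queries run at 0.9 through the initial
query and all refinement rounds except the last, which runs at 0.1;
intensity queries always run at 0.1. The exploratory temperature for the
*initial* fragment query is a deliberate reading: exploration belongs to
the generation phase, determinism to the final answer; the schedule is
configurable if a different convention is wanted.

## Assumptions and key design choices

- **Substructure semantics.** Heavy-atom subgraph isomorphism with
  hydrogen counts ignored and bond orders matched generically by default,
  so aromatic and kekulized forms of the same ring system agree.
  Fragmentation changes hydrogen counts, and strict H-matching would
  reject chemically true fragments. A `strict_bond_order` flag restores
  exact bond-order matching for users who want the stricter reading.
- **2-D identity key.** Canonical SMILES of the hydrogen-normalized
  skeleton (explicit hydrogens stripped, valences refilled implicitly,
  radicals cleared, charges kept). Two fragments with the same heavy-atom
  graph and bond orders share a key regardless of saturation state.
- **Fragment persistence (floor rule).** Fragments whose intensity
  entries are removed by cleaning re-enter at level 1 rather than
  vanishing: the fragment list is the peak skeleton of the spectrum, and
  cleaning an intensity should not silently delete a peak. The floor
  level is the smallest expressible value on the discretized scale.
- **Isomer merging.** Fragments that share an m/z value at the printed
  precision (isomers with equal formulas) are merged into one queried
  peak; the earlier-ranked fragment carries the peak label, and the full
  ranked fragment list is retained on the spectrum object. This preserves
  the unique-m/z invariant and avoids the pipeline rejecting its own
  duplicate queries. Accuracy metrics score the full fragment list, not
  the merged peak labels.
- **Dialects.** SMILES is the default molecular string dialect
  everywhere. SELFIES is supported behind an optional dependency and a
  `dialect="selfies"` switch for backends that prefer it; the choice does
  not affect the pipeline's contracts, only the serialization inside
  prompts and answers.

## Reference fragmenter

The ground-truth engine breaks bonds combinatorially on the kekulized
heavy-atom graph: one step cleaves a single acyclic bond, or a pair of
ring bonds (a lone ring cleavage leaves the graph connected and produces
no fragment). Both pieces of every cleavage are kept, open valences are
hydrogen-capped, and enumeration proceeds breadth-first to `max_depth`
(default 2), deduplicating by 2-D identity at the minimal depth. The
parent is the depth-0 member.

Peak labeling assigns each observed peak the fragment minimizing the
absolute mass error within a tolerance (default 0.01 Da), allowing a
±`h_shift` (default 1) hydrogen-mass rearrangement window to compensate
for the hydrogen-saturation model. These defaults are desk-scale choices
exposed in configuration; real annotation engines also apply curated
neutral-loss lists and score candidate assignments, which this engine
deliberately does not.

## Mock oracle

The mock backend answers fragment prompts with the reference fragmenter's
output sorted by a heuristic intensity (`mass_fraction`: level =
max(1, round(10 · m_fragment / m_parent)), i.e. heavier fragments are more
abundant; or `uniform`), and intensity prompts with the same heuristic.
Error injection is seeded and per-request deterministic (the RNG is keyed
on the config seed and a CRC of the prompt text): `corruption_rate`
replaces entries with an undecodable string or a valid-but-too-large
decoy (two disconnected copies of the parent, which can never embed in
it), and `drop_rate` omits entries.

The oracle emulates the *format* and *failure modes* of a generative
model: JSON payloads, order-by-intensity, invalid strings,
non-substructures, missing entries. It does not emulate chemistry-aware
plausibility (its intensity heuristic is monotone in mass, unlike real
fragmentation), response variability at high temperature, or free-text
wrapping. Passing tests therefore demonstrate that the orchestration,
filtering, cleaning, accounting and metrics are correct — not that any
particular language model fragments molecules well.

## QA dataset and curriculum

Each annotated spectrum yields exactly two QA pairs. The fragment answer
lists labeled fragments by descending observed intensity; the intensity
answer assigns levels obtained by discretizing base-peak-relative
intensities with half-away-from-zero rounding floored at 1 (so 0.04 → 1,
0.55 → 6, 1.0 → 10). Training files are chat-format JSONL sorted stably
by complexity = n_tokens/max(n_tokens) + n_fragments/max(n_fragments),
with the maxima taken over the set being ordered. The default token
counter is a whitespace-and-punctuation splitter; it is pluggable, and
relative ordering is robust to the choice. Upstream split columns are
honored and never re-split.

## Evaluation

Spectra are vectorized by summing intensities into half-open 0.01 Da bins
up to 1005 Da (configurable). Cosine similarity is the normalized dot
product (0 for an all-zero vector); Jensen–Shannon similarity is
1 − JSD of the sum-normalized vectors with base-2 logarithms, so
identical distributions score 1 and disjoint supports score 0. Fragment
accuracy is |generated ∩ reference| / |reference| on 2-D identity keys;
subformula accuracy is the same on deduplicated Hill formula strings —
deduplication on both sides keeps every percentage within [0, 100].
Run-level reports are unweighted means over query molecules.

## Fixture generator

Fixture libraries draw from a packaged list of 25 common small organics
(ethanol through caffeine, ~2–14 heavy atoms), place peaks at the exact
adduct m/z of the reference fragments with mass-fraction intensities, and
optionally add seeded Gaussian intensity noise and decoy peaks placed
≥0.2 Da away from every candidate m/z (so they are provably unlabelable
at the default tolerance). Generation is bit-reproducible per seed.
The library emulates annotated-library *structure* (molecule, settings,
peak lists, splits), not real fragmentation physics: real spectra contain
rearrangement products, multiply-charged ions, isotope peaks and
instrument noise that these fixtures do not.

## Problem sizes

The shipped verification runs use fixture libraries of 10–25 molecules at
fragmentation depth 1–2 and the mock backend's default schedule (8 calls
per molecule). These sizes exercise every code path — multi-ring systems,
isomer collisions, corruption recovery — while keeping any single run in
the seconds range; all of them are configuration, not limits.

## Known limitations

- The combinatorial fragmenter scales exponentially with depth; depths
  beyond 3 on molecules larger than ~25 heavy atoms become slow. Real
  annotation engines prune with scoring models; this one does not.
- Charged or zwitterionic query molecules are keyed with their charges
  preserved; protonation-state normalization is out of scope.
- Hosted-backend results depend on the provider's sampling determinism;
  the transcript recorder and replay backend exist precisely so such runs
  can be audited and replayed offline.
- The intensity floor rule and the isomer-merging policy are documented
  readings of underdetermined behavior; both are localized and
  configurable in code if different conventions are needed.
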