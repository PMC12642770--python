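# gifms

LLM-guided, peak-labeled tandem-MS spectrum simulation for small molecules.

## The problem

Annotating measured MS/MS spectra means matching them against reference
spectra — but reference libraries cover only a small fraction of chemical
space, so in-silico simulation of spectra for candidate molecules is a
central tool in metabolomics. Most simulators first propose molecular
fragments and then score their intensities. `gifms` implements a
*reasoning-based* variant of that paradigm: a chat-completion model is
guided, through structured prompts and iterative refinement, to propose
fragment substructures of a query molecule and then to assign discretized
peak intensities. Because every peak carries the substructure that
explains it, the output is directly interpretable and supports
human-in-the-loop workflows such as ranking candidate structures against
a query spectrum.

## The method

Given a query molecule M (SMILES, optionally SELFIES) and experiment
settings (adduct, instrument, collision energy):

1. **Fragment generation.** The backend is prompted with a tagged,
   instruction-style query (`<<FragmentListPrediction>>`, `<<MOL>>`,
   `<<EXP_SETTINGS>>`) to return a JSON array of fragment strings in
   order of descending intensity. Each response is filtered: entries that
   do not decode to a valid structure, or whose heavy-atom graph is not
   subgraph-isomorphic to M's, are removed. The survivors and the invalid
   count are embedded in a refinement prompt and the query repeats — by
   default 1 initial + 5 refinement rounds, at temperature 0.9 for the
   exploratory rounds and 0.1 for the final one.
2. **Offline m/z.** For each fragment F with monoisotopic mass m(F) and
   adduct with mass shift δ and charge z, the peak position is
   m/z = (m(F) + δ) / |z|. Mass arithmetic is never delegated to the
   language model.
3. **Intensity prediction.** The backend assigns each m/z an integer
   level on a 1–10 scale; responses are cleaned (unqueried m/z, duplicate
   m/z, and out-of-scale levels are dropped), merged onto the fragment
   list, and refined once. Levels map to relative intensities (level/10,
   renormalized to base peak 1.0); fragments whose entries were cleaned
   away persist at the floor level 1.

A deterministic **mock oracle** backed by a combinatorial MAGMa-style
reference fragmenter (acyclic bonds broken one at a time, ring bonds in
pairs, hydrogen-capped open valences) lets the whole pipeline run offline
— including configurable corruption/drop error injection to exercise the
filters. The same fragmenter provides ground-truth peak labels for
building instruction-tuning QA datasets (two pairs per annotated
spectrum: fragment generation and intensity prediction) with
curriculum ordering by complexity = normalized prompt tokens +
normalized fragment count.

Evaluation metrics: fragment accuracy and subformula accuracy against
the reference fragmenter, chemical and substructure validity of generated
strings, and binned cosine and Jensen–Shannon similarity (1 − JSD, base-2
logs) between spectra vectorized at 0.01 Da up to 1005 Da. A single-peak
precursor-m/z baseline is included for comparison.

## Worked example

```python
from gifms import (
    ExperimentSettings, GifRunConfig, MockBackend, MockOracleConfig,
    parse_molecule, simulate_spectrum,
)

mol = parse_molecule("CCO")  # ethanol
settings = ExperimentSettings(adduct="[M+H]+", instrument="Orbitrap", collision_energy=20.0)
backend = MockBackend(MockOracleConfig(fragment_depth=1))

spectrum = simulate_spectrum(mol, settings, backend, GifRunConfig())
for peak in spectrum.peaks:
    print(f"{peak.mz:9.4f}  {peak.intensity:5.2f}  {peak.label.smiles}")
print(f"backend calls: {backend.n_calls}")
```

prints

```
  17.0386   0.30  C
  19.0178   0.40  O
  31.0542   0.70  CC
  33.0335   0.70  CO
  47.0491   1.00  CCO
backend calls: 8
```

Five labeled peaks: the four depth-1 fragments of ethanol (methyl,
hydroxyl, ethyl and hydroxymethyl units, hydrogen-saturated) plus the
protonated parent at m/z 47.0491 as the base peak. Intensities follow the
mock oracle's mass-fraction heuristic. The call count is exact: 1 + 5
fragment queries and 1 + 1 intensity queries.

The same machinery is available from the shell:

```bash
gif fixtures --out fixtures.tsv --n-molecules 20 --noise-sd 0.05
gif simulate --library fixtures.tsv --out sim/
gif evaluate --library fixtures.tsv --out eval/
gif build-qa --library fixtures.tsv --out qa/
gif prep-finetune --pairs qa/pairs.jsonl --out finetune/
gif baseline --library fixtures.tsv --out baseline/
```

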