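# aplkit

Design and validation analytics for T-cell **super-agonist peptides**
(altered peptide ligands, APLs) derived from positional-scanning
combinatorial peptide library (PS-CPL) screens.

Tumour-associated antigens such as the HLA A2-restricted Melan-A/MART-1
decamer **EAAGIGILTV** are weak self-antigens: central tolerance removes the
highest-affinity TCRs, so vaccination with the natural sequence primes small
and often low-quality T-cell responses. One route around this is to screen a
tumour-reactive T-cell clone against a PS-CPL — mixture sublibraries fixing
one peptide position at a time — and use the resulting residue-preference
landscape to design APLs that activate the clone *better* than the natural
epitope (e.g. the super-agonist **MTSAIGILPV**, which differs from
EAAGIGILTV at five of ten positions yet primes larger populations of
natural-epitope-reactive T-cells). aplkit is for immunologists doing this
kind of epitope engineering: it covers the in-silico ranking step and the
quantitative analysis of every standard validation assay around it.

## What it computes

- **Scoring model** from a CPL screen: background-subtracted responses
  r(i,a) become per-position log-probabilities
  `w(i,a) = ln((r(i,a)+ε) / Σ_b (r(i,b)+ε))`; a peptide scores
  `Σ_i w(i, s_i)` (the PS-CPL position-independence assumption).
- **Exact top-k enumeration** of the full combinatorial universe (20¹⁰
  decamers) by best-first search — provably identical to brute-force
  enumeration, without materialising the universe — with shared-residue
  masks and Hamming distances against the index epitope.
- **Dose-response**: bounded 4-parameter-logistic fits
  (EC₅₀, hill slope) of MIP-1β/ELISpot titrations, and EC₅₀ fold changes.
- **Cytotoxicity**: reference-normalised flow killing,
  `100 − (exp T/exp ref)/(con T/con ref) × 100`, and chromium-release
  specific lysis `100·(E−S)/(M−S)`.
- **Priming statistics**: per-donor min-max heat bars of tetramer⁺
  percentages, paired one-tailed t-tests, CFSE proliferation above DMSO
  background, per-tetramer⁺-cell effector dosing, T2 stabilization indices.
- **Clonotype overlap**: shared CDR3s per chain, Jaccard indices, V-gene
  usage between peptide-primed lines (AIRR-style TSV input).
- **Structural mimicry** of two peptide–HLA complexes (PDB input): heavy-atom
  peptide–groove contacts under a strict 4.0 Å cutoff, peptide backbone RMSD
  in the groove frame (Kabsch superposition on groove Cα), and
  exposed/buried side-chain classification by Shrake–Rupley SASA.
- **Synthetic data** with planted ground truth for every input above, so the
  whole pipeline is testable end to end without any external data.

See `docs/methods.md` for the model details and design rationale.

## Worked example

Simulate a decamer screen of a synthetic clone and rank candidates:

```bash
$ aplkit simulate cpl --seed 7 --n-per-sublibrary 2000 --out screen.tsv
planted optimum: FESNIAFTLY
$ aplkit topk --cpl screen.tsv --k 5 --index-peptide EAAGIGILTV
rank    sequence    score       shared_mask  hamming
1       FESNIAFTLY  -23.222581  0000100000   9
2       FESNIAFHLY  -23.493944  0000100000   9
3       FESAIAFTLY  -23.597369  0000100000   9
4       FESIIAFTLY  -23.626567  0000100000   9
5       FESNIQFTLY  -23.650803  0000100000   9
```

The screen's planted optimum is recovered at rank 1; lower-ranked candidates
are single-position variants paying the corresponding weight difference.
Scores are log-probabilities (sums of per-position `w(i,a)`), so differences
between rows are log odds. The shared mask and Hamming distance compare each
candidate to the natural epitope given with `--index-peptide` (here only
position 5, `I`, coincides).

Assay formulas straight from event counts:

```bash
$ aplkit killing --exp-target 200 --exp-ref 1000 --con-target 500 --con-ref 1000
killing_percent 60.0000
$ aplkit chromium --experimental 500 --spontaneous 100 --maximum 900
specific_lysis_percent  50.0000
```

200 surviving targets per 1000 reference events versus 500 per 1000 in the
effector-free control means 60 % of targets were killed; a chromium well
halfway between spontaneous and maximum release is 50 % specific lysis.

The same operations are importable (`from aplkit import top_k,
fit_dose_response, flow_killing_percent, ...`), and `aplkit run
--config run.yaml` executes any subset of stages from one YAML config,
writing per-stage TSV reports plus a manifest with input digests, parameters
and seeds.

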