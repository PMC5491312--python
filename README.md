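# refield

Evolutionary energy fields for tandem-repeat protein families.

`refield` scores a pair of consecutive repeats `s` (length `L`, 21-state
alphabet: 20 amino acids + gap) with

```
E(s) = - Σ_i h_i(s_i) + Σ_{i<j} J_ij(s_i, s_j) - λ[k(s)]
```

where `k(s)` is the number of positions at which the two repeat halves carry
the same state. Lower energy means a sequence more compatible with the
family. The package covers the full workflow:

* **msa** — FASTA/Stockholm alignments of single repeats (PFAM-style
  `proteinID/start-end` headers), joining consecutive repeats into pairs,
  removing columns gapped in >80% of rows (jointly across the two halves of
  pair alignments), and greedy 90%-identity redundancy reduction.
* **stats** — single-site frequencies `f1`, joint frequencies `f2` (i<j) and
  the repeat-identity distribution `pid` over match counts `0..L/2`
  (gap–gap counts as a match), with an optional uniform pseudocount.
* **model** — parameter container with sparse-JSON serialization, energy
  evaluation (scalar, batch, incremental ΔE for mutation sets), repeat-array
  decomposition into per-repeat internal and per-interface interaction
  energies, and parameter counting (`L·q` fields, `((Lq)²−Lq)/2` couplings,
  `L/2+1` identity potentials).
* **sampler** — Metropolis Monte Carlo over the 21-state sequence space
  (numba-compiled kernel; accept if ΔE ≤ 0, else with probability
  `exp(−ΔE)`; thinned recording), plus uniform random-sequence negative
  controls.
* **inference** — Boltzmann-machine learning by stochastic gradient descent
  with an L1 proximal rule on couplings (dormant couplings activate only
  when the frequency gap exceeds γ; active couplings are shrunk and clipped
  to exactly zero on sign crossings). Stops when the largest deviation
  between empirical and model-sampled statistics drops below the tolerance.
* **analysis** — consensus sequences, energy-vs-identity tables, ΔΔG
  prediction from mutation tables (with declared sign conventions and
  fit-exclusion flags), extreme-coupling extraction and comparison against
  a precomputed binary contact map.
* **synthetic** — ground-truth model + alignment generators (sparse
  couplings, optionally planted on given position pairs; heavy-tailed
  identity potential) so the whole pipeline is testable offline.

## CLI

All functionality is exposed through the `ref` entry point:

```bash
ref synth --seed 1 -n 5000 --params-out truth.json --aln-out aln.fasta
ref msa pair repeats.fasta -o pairs.fasta
ref msa filter pairs.fasta -o filtered.fasta --max-gap 0.8
ref msa cluster filtered.fasta -o reps.fasta --id 0.9
ref stats reps.fasta -o stats.json --pseudocount 1e-5
ref fit --stats stats.json --out params.json --mc-n 20000 --tol 0.02 --seed 1
ref sample --params params.json -n 1000 --thin 1000 --seed 7 -o ensemble.fasta
ref score --params params.json --aln ensemble.fasta
ref analyze consensus --stats stats.json
ref analyze ddg --params params.json --table mutations.tsv
ref analyze couplings --params params.json --cmap contacts.txt --top 200 --bottom 200
```

Every stochastic subcommand is deterministic for a fixed `--seed`. Mutation
tables are TSV with columns `id, wt_sequence, mutations ("A12G;S30P"), ddG,
ddG_sd, convention (destab_positive|destab_negative), exclude`. Contact
maps are whitespace-delimited square 0/1 matrices; producing one from a
structure is a one-liner with any structural-bioinformatics library (e.g.
pairwise Cα/heavy-atom distance threshold on the repeat-pair residues).

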