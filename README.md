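# motifmix

Partition ChIP-reported DNA sequences into *binding modes*: disjoint groups
of sequences, each explained by its own de novo position weight matrix (PWM)
with its own learned width.  Many ChIP experiments mix direct binding,
co-factor recruitment and tethering, so a single motif model underfits; a
mixture with an automatically selected number of modes recovers the distinct
sequence signals in one run, without a motif database.

## How it works

- **Model.** Each sequence belongs to exactly one of `m` modes and carries
  exactly one motif site of that mode's PWM (one occurrence per sequence),
  on either strand; everything outside the site follows an order-2 Markov
  background fitted to the input.
- **Inference.** Collapsed Gibbs sampling: PWM entries and mode proportions
  are integrated out under Dirichlet priors, and the sampler draws only the
  discrete per-sequence assignments (mode, site position, strand) plus
  per-mode motif widths via grow/shrink column moves.  Each chain ends with
  a deterministic hill climb to a local MAP state.
- **Model selection.** The search runs several independently seeded chains
  for every mode count `m` in a range, keeps the best chain per `m`, and
  selects the `m` maximising `MAP log posterior − λ·|M_m|`, where
  `|M_m| = Σ_k 3·w_k + (m−1)` counts free parameters (default `λ = 5`).

See [docs/methods.md](docs/methods.md) for the full model, the collapsed
posterior, the convergence rule and a worked example.

## Command line

```bash
motifmix -f peaks.fasta -minMode 1 -maxMode 10 -r 5 -o results/
```

Key options (defaults in parentheses): `-minMode`/`-maxMode` mode-count
range (1/20), `-r` restarts per mode count (5), `-lambda` parameter-count
penalty (5), `-wInit`/`-wMin`/`-wMax` initial/min/max motif width
(12/6/40), `-seed` base seed (0), `-workers` parallel chains (0 = all
cores; the result is identical for any worker count), `-singleStrand`
search the given strand only, `-maxMasked` drop sequences with more
lowercase/ambiguous bases than this (150).

The output directory contains, for every `m` searched:

- `assignments_m{m}.tsv` — per sequence: mode, site start/end (1-based,
  inclusive), strand, and the site sequence (reverse-complemented for `-`);
- `pwm_m{m}_mode{k}.txt` / `counts_m{m}_mode{k}.txt` — the mode's PWM
  (posterior-mean probabilities) and raw aligned base counts;
- `summary_m{m}.tsv` — per-mode members, mixing proportion, width, consensus;

and at the top level `models.tsv` (per-`m` scores), `best_model.txt`,
`background.txt` (the fitted background, round-trippable), `index.html`
and `manifest.json`.

## Python API

```python
from motifmix import (read_fasta, filter_repeats, fit_background,
                      SearchConfig, ChainConfig, search_models)

seqs = filter_repeats(read_fasta("peaks.fasta"))
bg = fit_background(seqs, order=2, pseudocount=1.0)
result = search_models(seqs, bg, SearchConfig(m_min=1, m_max=10,
                                              chain=ChainConfig(m=1)))
print(result.best_m)
for mdl in result.best_mode_models():
    print(mdl.consensus(), mdl.members, mdl.gamma_hat)
```

`motifmix.synthetic` generates benchmark datasets with planted motifs and
scores recovery against the planted truth
(`generate_dataset`, `score_recovery`).

## Reproducibility

Every chain's seed is derived deterministically from
`(base_seed, m, restart)`, so results are a pure function of the inputs and
the base seed — independent of the worker count, and stable when the search
range or restart count is extended later.

## Testing

```bash
pip install --no-build-isolation -e '.[test]'
pytest
```

`tests/test_acceptance.py` holds end-to-end acceptance checks (exact oracle
identities for the collapsed arithmetic, bit-exact bookkeeping, hill-climb
monotonicity, planted-motif recovery with model selection, penalty
monotonicity, worker-count determinism).  A standalone study is available
via:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
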