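# File formats

All writers emit UTF-8 with LF line endings. Tables are tab-separated by
default; a comma delimiter is auto-detected on read from the header line.

## Run table (long format, one row per run × protein)

Column order: `run_id, bait_id, replicate, condition, protein_id, spc, intensities`

- `bait_id` — bait protein id, or the reserved token `CONTROL:<tag>`
  (e.g. `CONTROL:GFP`) for mock-control runs.
- `replicate` — positive integer replicate index.
- `spc` — non-negative integer spectral count.
- `intensities` — `;`-joined positive decimals (precursor-ion
  intensities), may be empty.

## Protein table

Column order: `protein_id, length, is_bait`

- `length` — amino acids, ≥ 1.
- `is_bait` — `1`/`0` (also accepts `true`/`false` on read; optional).

## Reference PPI table

Column order: `protein_a, protein_b, n_publications`

Pairs are canonicalized (unordered); duplicates merge by maximum
publication count; self-edges are kept with a warning.

## NSAF table (output)

Column order: `run_id, protein_id, nsaf` — long format, zero entries
omitted.

## Scores table (output)

Column order: `bait, prey, xbar, control_value, enrichment,
passed_enrichment, n, f, omega, wd, wdn, passed_wdn, is_hcip, rescued`

## Network exports

- **edge table** (`.tsv`): `bait, prey, wdn, enrichment, rescued, module,
  rel_abundance` plus any extra edge attributes.
- **SIF**: `bait<TAB>pp<TAB>prey`, one line per edge.
- **GraphML**: undirected graph with all edge attributes.

## Modules table (output)

Column order: `protein_id, module, kind` with `kind` in `{prey, bait}`.

## Quantification table (output)

Column order: `prey, mean_rel_a, mean_rel_b, log2fc, p_value, degenerate,
stars`.

## Pipeline config (YAML)

Top-level sections: `pipeline` (required; `rng_seed` mandatory),
`generator` or `inputs` (one required), `quant` (optional), `stages`
(optional booleans). Unknown keys anywhere are rejected. See
`PipelineConfig` and `GeneratorConfig` docstrings for the full key list
and defaults.
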