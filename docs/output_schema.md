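# Output schema

Units: Å = Angstrom; pLDDT and confidence on the 0–100 scale;
recoveries and probabilities are fractions in [0, 1].

## Per-step loss log (`<design_id>_loss.tsv`, from `hallucinate`)

| column | type | meaning |
|---|---|---|
| step | int | optimization step (0 = initial state) |
| total | float | weighted composite loss (dimensionless) |
| accepted | 0/1 | whether the step's proposal was accepted (always 1 for gradient steps) |
| `<term name>` | float | unweighted value of that loss term at this step (entropy/CE in nats; RMSD in Å; repulsion in [0,1]; rog in Å²; mean_pae in Å) |

## Design record (`<design_id>.json`)

| field | meaning |
|---|---|
| design_id | identifier used in file names and FASTA headers |
| contig | contig string (chain + 1-based inclusive ranges; gaps in residues) |
| placement | total_length, motif design positions, segment index map, realized gap lengths |
| sequence | final designed amino-acid sequence (one-letter) |
| structure_path | PDB file of the predicted coordinates; B-factor column = per-residue pLDDT (0–100, 2 decimals) |
| loss_breakdown | per term: value (unweighted), weight, weighted |
| metrics | plddt_mean (0–100), motif_rmsd (Å), and for complexes inter_pae (Å), target_aligned_rmsd (Å) |
| provenance | seed, stage list (optimizer, steps, loss config), config hash, tool version |

## Benchmark table (`inpaint-bench --out`)

| column | type | meaning |
|---|---|---|
| record_id | str | input structure identifier (PDB stem) |
| mask_index | int | mask number within the record |
| mask_start | int | 0-based window start |
| mask_length | int | window length in residues |
| fixed_region_rmsd | float, Å | Kabsch-superposed N/CA/C RMSD of the unmasked region vs the original |
| sequence_recovery | float, [0,1] | fraction of masked positions with the native letter recovered |
| masked_mean_confidence | float, 0–100 | mean completer confidence in the window (NaN if not reported) |

`<out>.summary.tsv` holds the same numeric columns averaged per record.

## Evaluation report (`evaluate --out`)

| column | type | meaning |
|---|---|---|
| design_id | str | record identifier |
| plddt_mean | float, 0–100 | mean per-residue confidence |
| motif_rmsd | float, Å | superposed backbone RMSD of the motif region vs native |
| inter_pae | float, Å | mean PAE over the two off-diagonal chain blocks (complexes only) |
| target_aligned_rmsd | float, Å | binder RMSD after target-only superposition (complexes only) |
| pass | bool | True iff every filter criterion holds (strict inequalities) |

## Acceptance results (`scripts/acceptance.py --out`)

JSON mapping quantity name → `{value, n}` where `n` is the problem size
used (instances, seeds, pairs or rows). Values are fractions for
recoveries, nats for entropies, Å for RMSD deviations, and counts for
motif sizes and filter flags.
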