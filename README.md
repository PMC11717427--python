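# metascreen

Meta-analysis of published gene lists and triage of predicted protein–protein
interaction models, as one tested pipeline:

1. **Ingest** (`metascreen.ingest`) — parse heterogeneous per-study gene
   tables, keep entries with (adjusted) P < 0.05 when values are reported,
   standardize gene names through a user-supplied alias map, and emit
   canonical gene lists (TSV + JSON manifest).
2. **Score** (`metascreen.occurrence`) — build the genes × lists incidence
   matrix, cull the top-*g* most frequent genes, and rank them with the
   selectivity-weighted regulation score `r_g = Σ_i S_i/T_i` (overlap of a
   gene set with each list, divided by list size).
3. **Cluster** (`metascreen.cooccur`) — Jaccard distances and average-linkage
   dendrograms over presence/absence vectors; historical mutual information
   (HMI, symmetric normalized mutual information) graphs linked at
   `1 − HMI ≤ 0.9`; Girvan–Newman communities (max-modularity partition
   along the edge-removal sequence).
4. **Simulate** (`metascreen.overlap`) — Monte-Carlo and exact hypergeometric
   probabilities of a random list overlapping a fixed top-gene set, plus a
   preferential-attachment list-growth model.
5. **Triage** (`metascreen.triage`) — load two-chain models (PDB/mmCIF +
   PAE JSON + score JSON), call constrained residue pairs (Cα distance
   < 6 Å and max inter-chain PAE < 5 Å), apply both criteria generations
   (v1: ranking > 0.6 and ≥ 20 constrained prey residues; v2: ranking > 0.6
   and n_bait × n_prey > 100), compute buried interface area
   (Shrake–Rupley), superposition RMSDs (Kabsch), cross-predictor interface
   concordance, and export interaction networks (GraphML/TSV).
6. **ORF scan** (`metascreen.orfscan`) — six-frame search for the longest
   stop-free peptide stretch in nucleotide FASTA.
7. **Synthetic data** (`metascreen.synth`) — seeded generators for list
   corpora with planted co-occurring gene blocks, dimer fixtures with
   planted contacts, and sequences with planted reading-frame runs, each
   with a machine-readable ground-truth sidecar.

## CLI

All stages are exposed through one entry point; every run writes its
resolved parameters as JSON next to its outputs.

```sh
# synthesize a corpus with a planted 4-gene block, then score and cluster it
metascreen synth corpus --n-genes 2000 --n-lists 100 --block 4:30:1.0 \
    --seed 7 --out corpus/
metascreen score --lists corpus/gene_lists.tsv --g 25 --out scored/
metascreen cluster --lists corpus/gene_lists.tsv --g 100 --threshold 0.9 \
    --out clustered/

# overlap probability simulation (closed form included in the summary)
metascreen simulate --n-genome 20000 --g 25 --t 100 --runs 100 --seed 1 \
    --out sim/

# triage a predicted dimer
metascreen synth dimer --n-pairs 25 --iptm 0.8 --ptm 0.55 --out fixture/
metascreen triage --coords fixture/dimer.pdb --pae fixture/dimer_pae.json \
    --scores fixture/dimer_scores.json --out call/

# six-frame scan
metascreen orfscan --fasta genes.fasta --out scan/
```

## File formats

* Gene lists: TSV with columns `list_id, source_id, category, gene`.
* Coordinates: PDB or mmCIF, exactly two chains.
* PAE: JSON with a square matrix under `pae` or `predicted_aligned_error`,
  ordered chain A residues then chain B.
* Scores: flat JSON `{"iptm": x, "ptm": y, "version": "AF2"|"AF3",
  "disorder_frac": z?}`; ranking = `0.8·ipTM + 0.2·pTM` (+ `0.5·disorder`
  for AF3-style models).
* Graphs: GraphML + edge-list TSV; dendrograms: Newick.
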