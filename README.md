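# spongenet

Inference of miRNA-mediated sponge (ceRNA) interaction networks from
matched expression profiles.

## The problem

Long non-coding RNAs can act as *competing endogenous RNAs* (ceRNAs, or
miRNA "sponges"): by harboring miRNA-recognition elements (MREs) they
sequester miRNAs and thereby derepress the miRNAs' mRNA targets. The
observable footprint of an active sponge relationship is a strongly
*positive* mRNA/lncRNA co-expression that collapses once the shared
miRNA is conditioned away. `spongenet` detects this footprint from
three matched expression matrices (mRNAs, lncRNAs, mature miRNAs over
the same samples) plus transcript sequences, and assembles the
resulting *miRNA-mediated interaction network* (MMI network). It is
aimed at computational biologists analyzing paired transcriptome /
small-RNA cohorts (e.g. tumor and matched normal tissue) and at method
developers who need a fully synthetic, ground-truthed benchmark for
ceRNA detection.

## The statistic

For a candidate triplet with expression profiles X (mRNA), Y (lncRNA)
and Z (miRNA), the first-order partial correlation

```
ρ_XY|Z = (ρ_XY − ρ_XZ ρ_ZY) / sqrt((1 − ρ_XZ²)(1 − ρ_ZY²))
```

measures what remains of the X–Y association after the computational
removal of Z. The **sensitivity correlation**

```
S = ρ_XY − ρ_XY|Z
```

is ≈ 0 for a direct X–Y interaction and approaches ρ_XY when the
association is routed through the miRNA. The pipeline:

1. filters genes (>10% missing values removed; mRNAs require a 3'UTR
   of ≥ 500 nt), partitions by biotype;
2. selects *cognate* mRNA/lncRNA pairs above the 99th percentile of the
   Pearson correlation distribution;
3. scores every (pair × miRNA) triplet and keeps S > 0.3, classifying
   each as a *pure sponge* module (ρ_XZ < 0) or *mixed TF-sponge*
   module (ρ_XZ > 0);
4. requires both partners to carry ≥ 1 exact 6-mer seed site (reverse
   complement of mature miRNA positions 2–7; mRNAs scanned over the
   3'UTR, lncRNAs over the whole transcript) and tests per-miRNA seed
   enrichment with an upper-tail hypergeometric test;
5. builds the lncRNA/mRNA multigraph whose edges are miRNA-labeled
   triplets, with pair weights (shared-miRNA counts), hubs, connected
   components, relationship profiles and mediation statistics.

A linear-Gaussian synthetic generator plants pure sponge triplets,
mixed modules, direct co-expression confounders and seed sites with an
exact ground-truth ledger, so the whole pipeline is testable without
any download.

## Worked example

```python
import spongenet as sp

cfg = sp.SyntheticConfig(rng_seed=42)          # 200 samples, 20 planted sponges
ds = sp.generate_dataset(cfg)

corr = sp.pearson_matrix(ds.mrna, ds.lncrna, compute_p=False)
pairs = sp.select_top_pairs(corr, percentile=99)
print(f"cognate pairs: {len(pairs)} at realized cutoff r >= {pairs.threshold_r:.3f}")

scan = sp.scan_triplets(pairs, ds.mrna, ds.lncrna, ds.mirna)
selection = sp.select_triplets(scan, mode="fixed", s_threshold=0.3)
print(f"triplets scanned: {scan.n_triplets}, selected with S > 0.3: {len(selection)}")

index = sp.build_seed_index(ds.seeds, ds.utr3, ds.lnc_tx)
net = sp.build_mmi_network(selection.frame, index)
print(f"MMI network: {net.n_nodes} nodes, {net.n_edges} edges")

for i, c in enumerate(sp.connected_components(net)[:3], 1):
    print(f"component {i}: {c.n_nodes} nodes / {c.n_edges} edges, "
          f"dominant miRNA {c.dominant_mirna} ({c.dominant_share:.0f}% of edges)")
```

prints

```
cognate pairs: 181 at realized cutoff r >= 0.185
triplets scanned: 5430, selected with S > 0.3: 80
MMI network: 40 nodes, 80 edges
component 1: 8 nodes / 16 edges, dominant miRNA mir_0001 (100% of edges)
component 2: 8 nodes / 16 edges, dominant miRNA mir_0002 (100% of edges)
component 3: 8 nodes / 16 edges, dominant miRNA mir_0003 (100% of edges)
```

The 181 selected pairs are the top 1% of all 18,000 mRNA×lncRNA
correlations; the 80 surviving edges are exactly the pairs coupled to a
planted mediator miRNA with seed support in both partners (none of the
20 planted direct co-expression confounders survives), and the network
decomposes into one component per mediator, each fully dominated by its
miRNA.

The same run is available from the shell:

```sh
spongenet simulate --seed 42 --outdir data/
spongenet run --config config.yaml
```

where `config.yaml` points at the emitted bundle; individual stages
(`filter`, `correlate`, `select-pairs`, `sensitivity`, `seed-scan`,
`enrich`, `build-network`, `net-stats`) are also exposed as composable
subcommands over TSV intermediates.

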