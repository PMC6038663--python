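# dcsnet

Prediction of lncRNA–disease association scores from a tripartite
disease–miRNA–lncRNA network, **without** using any known
lncRNA–disease associations for scoring.

Given two bipartite edge lists — disease–miRNA associations and
miRNA–lncRNA associations — the pipeline:

1. normalises and deduplicates names (merging miRNA locus copies that
   produce the same mature miRNA) and restricts both tables to their
   shared miRNA space (`io_tables`);
2. computes miRNA contribution weights `-log_b(deg(m)/|E|)` and
   shared-miRNA functional similarity matrices for diseases (base-10)
   and lncRNAs (base-2) on the *full* tables (`similarity`);
3. builds the tripartite adjacency matrix (diseases, then miRNAs, then
   lncRNAs) and its shortest-path matrix capped at a radius `r`
   (default 6), from which each node's distance correlation set is
   read (`hetnet`);
4. converts capped distances to coefficients `1 - k/(r+1)`, forms the
   distance-correlation-coefficient matrix (diagonal `r/(r+1)`),
   averages its row/column mass into association degrees, and takes
   the disease×lncRNA block `C13` as the raw prediction; the final
   score is `FSD · C13 · FSL` (similarity blending can be disabled)
   (`scoring`);
5. evaluates rankings with a leave-one-out protocol against a
   gold-standard table used *only* for evaluation: tie-corrected
   rank-statistic AUC, ROC points, per-pair ranks, a two-arm
   similarity ablation, and top-fraction prediction lists
   (`evaluation`).

A synthetic generator (`synthetic`) produces all three tables with a
configurable planted signal (gold pairs wired to shared miRNA
neighbourhoods), so the whole pipeline is testable offline.

## CLI

```sh
# generate synthetic tables (dm.tsv, ml.tsv, gold.tsv + manifest.json)
dcsnet simulate --n-diseases 20 --n-mirnas 40 --n-lncrnas 25 \
    --p-dm 0.05 --p-ml 0.05 --n-gold 10 --signal-overlap 4 \
    --seed 1 --out-dir runs/sim

# full scoring pipeline -> fad.tsv
dcsnet score --dm runs/sim/dm.tsv --ml runs/sim/ml.tsv -r 6 --out-dir runs/score

# leave-one-out evaluation -> ranks.tsv, roc.tsv, summary.txt
dcsnet loocv --dm runs/sim/dm.tsv --ml runs/sim/ml.tsv \
    --gold runs/sim/gold.tsv --ablation --out-dir runs/loocv

# top 0.5% of all disease-lncRNA pairs
dcsnet predict-top --dm runs/sim/dm.tsv --ml runs/sim/ml.tsv \
    --gold runs/sim/gold.tsv --fraction 0.005 --out-dir runs/top
```

Inputs are 2+ column TSV edge lists (`name<TAB>name`), `#` comments
skipped. Defaults reproduce the headline configuration: `r = 6`,
similarity blending on, global ranking pool, fraction 0.005. A YAML/JSON
config file can supply defaults (`dcsnet --config cfg.yaml score ...`);
explicit flags win. Every run writes a `manifest.json` with all
parameters and input checksums. Exit codes: 0 success, 1 usage error,
2 data/IO error.

## Notes

- The shortest-path matrix encodes "farther than r" as 0; consumers
  treat 0 as *no relation*, never as distance zero.
- Scores are unnormalised; only their ranking is meaningful.
- Two readings of the similarity formula are implemented
  (`exp(S/Q)` — default — and `exp(S)/Q`), selectable via
  `--convention`.
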