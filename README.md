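# circamotif

Circadian cis-regulatory motif discovery in TSS-anchored promoter windows.

Gene promoters of clock-controlled genes carry short DNA elements bound by
circadian transcription factors: E-boxes (CACGTG, bound by CLOCK/BMAL1-type
activators; degenerate form CANNTG), D-boxes (TTATG[TC]AA, DBP family), the
cAMP response element CRE (TGACGTCA, CREB), the insect Pdp1 core
(ATTTAT/ATAAAT) and the PER-repeat core (CATAC/GTATG). `circamotif`
implements the in-silico side of asking whether a promoter — the motivating
case is the 3 kb window upstream of the honeybee (*Apis mellifera*)
melatonin-receptor gene *AmMTR*, TSS at NC_037647.1:5,949,179 (Amel_HAv3.1)
— contains such elements, where they sit relative to the TSS, and whether
they are more frequent than a background model predicts.

The pipeline has four stages:

1. **Extraction** — pull the `L` bases immediately 5′ of a user-supplied TSS
   (default `L` = 3000). Positions are reported TSS-relative: the window
   covers −L…−1, negative = upstream, TSS base excluded.
2. **PWM scan** — parse JASPAR-format position frequency matrices, convert
   to log₂-odds weights `w_bj = log2(f_bj / p_b)` with corrected frequencies
   `f_bj = (n_bj + κ·p_b) / (N_j + κ)` (pseudocount κ = 0.8, background
   `p` uniform by default), and keep windows whose min–max **relative score**
   `(s − s_min)/(s_max − s_min)` is ≥ 0.85, on both strands.
3. **Consensus scan** — exact/degenerate IUPAC core matching for the six
   bundled circadian families (+ strand reporting convention; degenerate
   E-boxes coinciding with canonical ones are not double-counted).
4. **Enrichment** — per-family empirical test: observed counts against `n`
   (default 999) sequences resampled from a zero- or first-order Markov
   model, `p = (1 + #{null ≥ obs}) / (1 + n)`, Benjamini–Hochberg corrected.

A synthetic-promoter generator produces Markov backgrounds purged of motif
cores, plants sites at chosen TSS-relative positions (including the
published *AmMTR* site layout) and emits a truth table, so the whole
pipeline is testable without genome downloads.

## Worked example

Generate a 3 kb synthetic promoter carrying the published *AmMTR* site
layout on a purged uniform background, then scan it:

```sh
$ circamotif simulate --seed 7 --out-prefix fix
wrote fix.fa / .truth.tsv / .meta.json (12 planted site(s))

$ circamotif report --fasta fix.fa --out-prefix run
 -2762  Ebox_degenerate  +  consensus
 -2701  Dbox             +  consensus
 -2498  Dbox             +  consensus
 -1580  Ebox_degenerate  +  consensus
 -1383  Ebox_degenerate  +  consensus
 -1334  Ebox_canonical   +  consensus
  -820  Pdp1             +  consensus
  -457  Dbox             +  consensus
  -357  Pdp1             +  consensus
  -132  Dbox             +  consensus
  -102  Pdp1             +  consensus
   -93  CRE              +  consensus
total 12 hit(s): consensus=12
```

Every planted site is recovered at its exact TSS-relative position: the
three clustered Pdp1 cores at −820/−357/−102, four D-boxes, three
degenerate E-boxes, the canonical E-box at −1334 and the CRE at −93.
`run.bed`, `run.hits.tsv` and `run.report.json` hold the same hits in BED6
(0-based half-open genomic), TSV and JSON form.

Testing enrichment of the same fixture against an order-0 Markov null
fitted to the promoter itself:

```sh
$ circamotif enrich --promoter fix.fa --n 999 --seed 17
family           observed  null_mean  null_sd   p_raw  q_adj   enriched
Ebox_canonical   1         0.735736   0.847154  0.527  0.7905  False
Ebox_degenerate  3         11.022     3.21437   1      1       False
Dbox             4         0.1001     0.316529  0.001  0.006   True
CRE              1         0.0570571  0.236346  0.057  0.171   False
Pdp1             3         1.5035     1.26924   0.192  0.384   False
PER_repeat       0         5.86086    2.3969    1      1       False
```

Reading the table: four D-boxes against an expectation of ~0.1 per 3 kb is
significant after BH correction (q = 0.006); three Pdp1 cores against an
expectation of ~1.5 is not (p = 0.19) — presence of a short, common core is
weak evidence by itself, which is exactly why the formal test exists. The
degenerate E-box count sits *below* its null mean because the purged
background removes CANNTG everywhere except the planted sites.

To run against real genomic data, extract the promoter from a local FASTA
of the chromosome/scaffold (e.g. the NC_037647.1 sequence from NCBI) and
scan it:

```sh
circamotif extract --fasta NC_037647.1.fa --tss 5949179 --upstream 3000 \
    --strand + --out ammtr_promoter.fa
circamotif report --fasta ammtr_promoter.fa --motifs jaspar_pfms.txt \
    --out-prefix ammtr
```

## Library surface

```python
from circamotif import (
    read_fasta, extract_promoter,          # sequence_io
    parse_jaspar, pfm_to_pwm, scan_pwm,    # pwm_model
    default_families, scan_consensus,      # consensus_scan
    fit_markov, motif_enrichment,          # enrichment
    make_fixture, ammtr_layout,            # synthetic_data
)
```

See `docs/methods.md` for the model details, parameter defaults and known
limitations.
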