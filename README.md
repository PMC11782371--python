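# glycopath

Expression-guided analysis of glycan biosynthesis pathways.

Glycan synthesis is not template-driven: which structures a cell can make
is determined by which glycosyltransferase and glycosidase genes it
expresses.  `glycopath` maps RNA-seq gene-expression profiles (TPM) onto
curated glycan-biosynthesis reaction networks and answers, offline and
reproducibly:

* **Which reactions are on?**  Every reaction carries a boolean gene
  requirement — OR across isoenzymes, AND across complex subunits
  (`MAN1A1|MAN1A2|MAN1C1`, `GANAB&PRKCSH`).  Its score is the aggregated
  TPM (max over OR, min over AND by default; mean/min/max selectable) and
  is classified against a threshold of **1 TPM**: *expressed* (black
  arrow, width ∝ log expression), *limited* (red), *absent* (pink), or
  *unknown* (gray dashed, no identified enzyme).
* **Which glycans can be made?**  Three-state reachability: a structure is
  *present* if some root-to-structure path uses only expressed reactions,
  *rare* if every usable path crosses a limited/unknown step, *absent*
  otherwise.
* **What changed between two samples?**  Per-reaction fold change
  `(s_b+ε)/(s_a+ε)` with highlights for more-than-double (dark pink) and
  less-than-half (green).
* **How much of each product?**  An absorbing Markov chain with transition
  probabilities proportional to reaction scores; absorption masses
  `B = (I−Q)⁻¹R` give the quantitative glycan output profile, and expected
  visit counts and in-silico knockdown scans come for free.
* **What threshold should I use?**  ROC calibration against
  presence/absence labels: exact Mann–Whitney AUC, operating point by
  Youden's J or F1.

Three pathway definitions ship with the package: a compact N-glycan
processing map (including the bisecting-GlcNAc "Step 15" catalyzed by
MGAT3), a reconstructed human-milk-oligosaccharide network (39 core
structures, 6 terminal modifications, 30 genes) and a queuosine-tRNA
glycosylation stub (QTGAL/QTMAN).  See `docs/methods.md` for the model,
its assumptions and its limits.

## Worked example

Score an HEK293-like profile (all fixture genes at 10 TPM, MGAT3 at 0.4)
against the packaged N-glycan map:

```sh
$ cat hek_like.tsv
gene    hek_like
B4GALT1 10.0
...
MGAT3   0.4
...

$ glycopath visualize -e hek_like.tsv --sample hek_like \
    --out-svg map.svg --out-json scores.json
$ glycopath estimate -e hek_like.tsv --out-json presence.json
$ glycopath markov   -e hek_like.tsv --out-json profile.json
```

`scores.json` classifies every reaction; the only non-black arrow is the
bisecting-GlcNAc step, whose gene sits below the 1-TPM threshold:

```json
{"reaction_id": "r09", "score": 0.4, "klass": "limited", "color": "red", "width": 1.0}
```

`presence.json` propagates that bottleneck: exactly the bisecting branch
is called *rare* (`GNGN_BIS`, `GAL_BIS`, `SIA_BIS`), everything else
*present* — i.e. this cell makes few bisected N-glycans but all other
products of the map.  `profile.json` quantifies it with the absorbing
chain (masses over terminal structures):

```json
{"SIA3_B4": 0.3289, "SIA3_B6": 0.3289, "SIA_F": 0.3289, "SIA_BIS": 0.0132}
```

The three fully expressed branches split the remaining flux evenly while
the bisected product receives 1.3% — the quantitative counterpart of the
red arrow.  `glycopath compare` highlights fold changes between two
samples, and `glycopath calibrate` sweeps TPM thresholds against
presence/absence labels (or a built-in synthetic recovery harness) and
reports the ROC with Youden- and F1-optimal thresholds.

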