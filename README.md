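# bionlpeval

A self-contained toolkit for working with event-structure annotations in
the BioNLP Shared Task standoff format, covering the Cancer Genetics (CG)
and Pathway Curation (PC) task settings: parsing and validation, the
official matching criteria and micro-averaged precision/recall/F scoring,
approximate-randomization significance testing between systems, and a
synthetic-corpus generator with analytically predictable perturbations.

It is aimed at people who build or evaluate biomedical event extraction
systems — the structured "who did what to what" layer over entity mentions
(gene products, chemicals, cells, anatomical structures) that represents
statements like *MDM2 blocks p53 expression* as a `Negative_regulation`
event whose `Theme` is a `Gene_expression` event and whose `Cause` is an
entity mention.

## The evaluation model

Documents are triples `<id>.txt` / `<id>.a1` / `<id>.a2`: plain text, the
*given* layer (entity mentions, `Equiv` alias relations), and the *target*
layer (event triggers, events, `Negation`/`Speculation` modifications),
all referencing the text by 0-based end-exclusive character offsets.

A predicted event matches a gold event under the **primary criteria** iff

* the event types are equal,
* the trigger spans agree up to one word on each side (word = maximal
  alphanumeric run), and
* the argument multisets correspond one-to-one per role, where entity
  fillers are interchangeable within an `Equiv` equivalence class and
  event-valued fillers are compared recursively **on core arguments
  only** (the roles listed as core in the task's type tables).

With gold-matched counts `TP_g` of `|G|` gold events and matched predicted
counts `TP_p` of `|P|` predictions pooled over all documents and types
(micro-averaging),

```
R = 100·TP_g/|G|,   P = 100·TP_p/|P|,   F = 2PR/(P+R)
```

Two published relaxations are implemented: **core targets** (strip all
non-core arguments and modifications from both sides, merge the resulting
duplicates) and the **single partial penalty** (a prediction that differs
from a gold event only by extra arguments costs one false positive but no
false negative, and vice versa for missing arguments). System pairs are
compared with the stratified **approximate randomization** test (default
9,999 repetitions): per-document outputs are swapped with probability ½
and the permuted grand-total |ΔF| is compared with the observed one,
`p = (r+1)/(R+1)`.

Both task schemas (CG: 18 entity types, ~40 event types in six reporting
categories; PC: 4 entity types, SBO-aligned event inventory) ship built-in
and are exportable to YAML, so the role constraints and filler-category
tables can be adjusted without code changes.

## Worked example

`examples/score_predictions.py` generates a 10-document synthetic CG
corpus, corrupts it (15% event deletions, 20% dropped arguments) to play
the role of a system output, and scores it:

```
label                 gold  gold_matched  pred  pred_matched  recall  precision  fscore
...
Sub-total               76            37    53            37   48.68      69.81   57.36
Negation                 3             3     3             3  100.00     100.00  100.00
Speculation              3             1     1             1   33.33     100.00   50.00
Modification total       6             4     4             4   66.67     100.00   80.00
TOTAL                   82            41    57            41   50.00      71.93   58.99

     primary: R=50.00 P=71.93 F=58.99
 primary+spp: R=50.00 P=94.74 F=65.45
```

Deleted events cost recall; events with dropped arguments count as both a
false negative and a false positive under the primary criteria, which is
why the single partial penalty raises precision (the false positives of
merely-incomplete predictions are waived) while recall is unchanged.

The other examples parse and validate a hand-written document triple
(`parse_and_validate.py`) and run the significance test between two
synthetic systems (`compare_systems.py`). The same operations are
available from the shell:

```
bionlpeval generate --task CG --out gold/ --seed 1
bionlpeval evaluate --task CG --gold gold/ --pred pred/ [--core] [--spp]
bionlpeval compare  --task CG --gold gold/ --pred-a a/ --pred-b b/ --seed 7
bionlpeval validate --task CG --strict gold/
```

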