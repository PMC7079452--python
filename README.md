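# charqsar

Character-level SMILES modeling for QSAR with built-in interpretability:

1. **Canonicalization pretraining** — a sequence-to-sequence Transformer
   (pure NumPy, local autodiff engine in `charqsar.nn`) learns to map
   arbitrary SMILES writings of a molecule to its canonical form.
2. **Dynamic embeddings** — the frozen encoder turns a SMILES of N
   characters into an (N+2, d_model) matrix (start/end markers included),
   one context-dependent row per character.
3. **TextCNN QSAR head** — per-kernel 1D convolutions (kernel sizes
   1–10, 15, 20), global max pooling, dropout, dense, highway and a one-
   or two-neuron output, trained with Adam, SMILES augmentation and
   parent-level early stopping. Inference averages predictions over
   augmented SMILES (consensus); the spread estimates confidence.
4. **Layer-wise relevance propagation** — the prediction is decomposed
   back through the head (epsilon rule for dense/conv, winner-take-all
   for the max-pool, signal-take-all for the highway gate) down to the
   encoder output positions. Every backward step is logged in a ledger
   (incoming relevance, outgoing relevance, delta, bias share); a
   warning is raised when less than 50% of the signal reaches the input.
   Per-atom attributions are obtained by rooting one SMILES at every
   heavy atom, propagating each, and averaging the relevance collected
   on each atom's characters.

Chemistry (canonicalization, enumeration, atom-rooted SMILES) is
delegated to an injected oracle: an RDKit-backed implementation and a
dependency-free grammar oracle over acyclic toy molecules
(`charqsar.synthetic_fixtures`) that also generates seeded toy libraries
and planted-property datasets, so the whole pipeline is testable offline.

## Test

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria, including two
stochastic desk-scale experiments (a tiny canonicalizer reaching >=80%
exact-match restoration, and attribution recovery of a planted
halogen-count rule). The full suite runs in a few minutes on one CPU.

Full-scale results from the original setting (large-corpus
canonicalization rates, external benchmark r2/AUC, reference
mutagenicity/solubility figures) need millions of training pairs and
released weights; they are out of desk scope and are replaced by the
desk-scale experiments above.

## CLI

```bash
charqsar fixtures   --n 300 --seed 1 --out-dir fx/
charqsar make-pairs --molecules fx/library.txt --out pairs.txt --n-augment 10 --seed 1
charqsar pretrain   --pairs pairs.txt --epochs 5 --seed 1 --d-model 32 \
                    --n-layers 1 --n-heads 4 --batch-size 4 --out enc
charqsar train      --data fx/qsar.csv --encoder enc --task regression \
                    --augment 10 --seed 1 --out qsar
charqsar predict    --data fx/qsar.csv --model qsar --augment 10 --seed 1 --out pred.csv
charqsar evaluate   --pred pred.csv --task regression
charqsar interpret  --smiles "CC(Cl)CO" --model qsar --out attr.json --ledger-csv ledger.csv
```

Use `--oracle rdkit` on `make-pairs`/`train`/`predict`/`interpret` for
real chemistry instead of the toy grammar.

## Layout

```
src/charqsar/
  nn/                  reverse-mode autodiff core, layers, Adam
  tokenizer_io.py      66-symbol character vocabulary, pair files, QSAR CSV
  augmentation.py      oracle interface, RDKit oracle, enumeration policies
  synthetic_fixtures.py toy libraries, grammar oracle, planted datasets
  canonicalizer.py     seq2seq Transformer, LR schedule, decoding, report
  embedding.py         frozen-encoder dynamic embeddings
  qsar_textcnn.py      CNN head, training with early stopping, persistence
  inference_metrics.py consensus prediction, r2, AUC, bootstrap SEM
  lrp.py               relevance rules, ledger, char->atom map, attribution
  cli.py               command-line entry points
```
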