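# pepspr

Sequence-structure classification of missense variants. `pepspr` predicts a
binary property of an amino-acid substitution (AAS) — in the motivating
application, whether a substitution in a drug-target kinase such as ABL1
confers resistance to an inhibitor like imatinib or dasatinib — from nothing
but the protein sequence and a set of labeled substitutions.

The method treats each substitution as a chemical structure rather than a
feature vector. For every labeled substitution it:

1. cuts the **mutant peptide window** of odd length *L* (3–31) centered on
   the substituted residue,
2. assembles its **structural formula**: an explicit-hydrogen molecular
   graph built from neutral amino-acid templates joined by peptide bonds
   (readable/writable as SD files in MOL V2000/V3000),
3. describes it by **MNA descriptors** (Multilevel Neighborhoods of Atoms):
   recursively defined atom-centered substructure strings,
   `mark(D₁D₂…)` to a chosen level 0–15, ignoring bond types,
4. scores it with a **PASS-style naive-Bayes classifier**

       S₀ = 2P(A) − 1,   S = sin( meanᵢ asin(2P(A|Dᵢ) − 1) ),
       B  = (S − S₀)/(1 − S·S₀),

   with frequency estimates P(A) = Nk/N, P(A|Dᵢ) = Nik/Ni, and calibrates
   B into **Pa/Pi** (membership in the resistant / non-resistant class) via
   leave-one-out score distributions; the default decision rule is
   **Pa > Pi**, and the count of query descriptors never seen in training
   serves as an applicability-domain indicator.

Model selection follows the method's own protocol: a grid over window
length × descriptor level scored by leave-one-out ROC AUC, plus stratified
20-fold cross-validation, threshold scans (Pa > Pi and Pa > 0.3…0.9) and
confusion-matrix metrics. A seeded synthetic generator plants a learnable
sequence-context signal so the whole pipeline is testable without any
external data. See `docs/methods.md` for the model details and conventions.

## Worked example

```python
from pepspr import (SyntheticSpec, generate_dataset, build_dataset,
                    train_model, loo_auc, extract_window,
                    assemble_peptide_graph)

spec = SyntheticSpec(seed=1)            # 660 substitutions, ~13% positive
seq, records = generate_dataset(spec)
ds = build_dataset(seq, records, "resistance", length=5)
print(f"{len(ds)} windows, {ds.positives} resistant / {ds.negatives} non-resistant")

model = train_model(ds, level=3)
print(f"LOO AUC: {loo_auc(ds, 3):.3f}")

pos = next(r for r in records if r.labels["resistance"])
query = assemble_peptide_graph(extract_window(seq, pos, 5))
res = model.predict_graph(query)
print(f"{pos.name}: B={res.b:+.3f} Pa={res.pa:.3f} Pi={res.pi:.3f} "
      f"new descriptors: {res.n_new_descriptors}/{res.n_descriptors}")
```

prints

```
660 windows, 85 resistant / 575 non-resistant
LOO AUC: 0.943
K6V: B=+0.264 Pa=0.388 Pi=0.071 new descriptors: 0/72
```

The AUC of 0.943 says the leave-one-out B-scores rank a random resistant
substitution above a random non-resistant one 94% of the time. The K6V
query (a resistant training example) gets Pa well above Pi — predicted
resistant — and all 72 of its level-3 descriptors were seen in training,
i.e. the query is inside the model's applicability domain.

The same workflow is available from the shell:

```sh
pepspr simulate --seed 1 -o run/
pepspr build-dataset --fasta run/protein.fasta --table run/substitutions.tsv \
       --endpoint resistance --length 5 -o run/sdf/
pepspr train    --fasta run/protein.fasta --table run/substitutions.tsv \
       --endpoint resistance --length 5 --level 3 -o run/
pepspr predict  --model run/model_resistance_len5_lvl3.json \
       --sdf run/sdf/peptides_len5.sdf -o run/
pepspr cv --fasta run/protein.fasta --table run/substitutions.tsv \
       --endpoint resistance --length 5 --level 3 --k 20 -o run/
pepspr grid --fasta run/protein.fasta --table run/substitutions.tsv \
       --endpoint resistance -o run/
```

Every subcommand writes a `run-manifest.json` capturing its resolved
configuration.

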