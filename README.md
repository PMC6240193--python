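# mhc2lig

Prediction of MHC class II natural ligands from mixed training data —
in vitro peptide binding affinities (BA) and mass-spectrometry eluted
ligands (EL) — with binding-core alignment, antigen-processing context
features, and analysis of the proteolytic footprints at ligand termini.

MHC class II molecules present 11–19-residue peptides to CD4+ T cells
through an open-ended groove that binds a 9-residue core (anchors P1, P4,
P6, P9). Affinity data measures binding alone; eluted ligands additionally
encode antigen processing — most visibly a proline enrichment at the second
residue from either ligand terminus when the flanking region is long enough
to be trimmed. `mhc2lig` trains a single shallow network with one output per
data type and shared hidden weights, aligning each peptide's binding core
during training (arg-max over core placements, with a hydrophobic-P1
burn-in), and can present each ligand's ±3-residue source-protein context to
the network. A matched synthetic-data generator plants a known motif, length
law and cleavage signal so that every stage — alignment, mixed training,
metrics, footprint extraction — is testable against ground truth without
external data sets.

The package is aimed at computational immunologists building or probing
class II presentation models: the estimator surface is scikit-learn style,
and a small CLI covers the simulate → train → predict / evaluate /
footprint pipeline.

## Worked example

```python
import numpy as np
from mhc2lig import (MHCIILigandPredictor, WorldConfig, make_world,
                     emit_ligands, emit_ba, build_training_set, auc01)

world = make_world(WorldConfig(n_ligands=800, n_ba=400, seed=1))
ligands, proteome, truth = emit_ligands(world)
ba = emit_ba(world)
training = build_training_set(ligands, proteome, ba=ba, rng=1)

est = MHCIILigandPredictor(seeds=1, hidden_sizes=(10,), iterations=40)
est.fit(training.instances)

is_el = np.array([p.data_type == "EL" for p in training.instances])
y = np.array([p.target for p in training.instances])[is_el]
print("out-of-fold EL AUC0.1:", round(auc01(y, est.oof_el_[is_el]), 3))

true_off = np.array([rec["core_offset"] for rec in truth])
rec = (est.oof_offset_[: len(ligands)] == true_off).mean()
print("exact core recovery:", round(float(rec), 3))

print(est.predict_detail([ligands[0].sequence]).to_string(index=False))
```

Output:

```
out-of-fold EL AUC0.1: 0.882
exact core recovery: 0.979
            peptide      core  offset  score_el  score_ba
MVLFIMVFEIWQRDYDDPN MVFEIWQRD       5   0.92565  0.849729
```

The cross-validated AUC0.1 of 0.88 says the eluted-ligand head separates
true ligands from random proteome peptides already at 10% false-positive
rate; core recovery of 0.98 means the arg-max alignment found the planted
9-mer register for 98% of ligands; the per-peptide table reports the
selected binding core and both heads' scores.

The same pipeline from the shell:

```bash
mhc2lig simulate --n-ligands 800 --n-ba 400 --seed 1 --out sim/
mhc2lig train --ligands sim/ligands.tsv --ba sim/ba.tsv \
              --proteome sim/proteome.fasta --seeds 1 --hidden 10 \
              --iterations 40 --out model/
mhc2lig predict --model-dir model/ --peptides peps.tsv --out pred.tsv
mhc2lig footprint --model-dir model/ --ligands sim/ligands.tsv \
                  --proteome sim/proteome.fasta --out fp/
```

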