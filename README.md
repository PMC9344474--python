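# watblocks

Knowledge-based prediction of DNA hydration from **hydrated dinucleotide
building blocks**.

Ordered water molecules are an integral part of DNA structure: the spine of
hydration in the B-DNA minor groove, the cones of hydration around phosphate
oxygens and the dense water networks of A- and Z-form duplexes are all
sequence- and conformation-dependent. `watblocks` derives these patterns
empirically from a corpus of DNA crystal structures and uses them to predict
the first hydration shell of any DNA coordinate model.

## Method

1. **Curation** — DNA chains are filtered (resolution ≤ 2.6 Å, more than
   1.0 observed waters per nucleotide counted within 3.4 Å of the chain
   including symmetry mates, length ≥ 6 nt) and clustered by sequence
   (chains shorter than 24 nt may differ at 2 positions and still be
   redundant); each cluster keeps its best-resolution member, with the
   water count breaking ties within ±0.1 Å.
2. **Blocks** — every chain is split into overlapping dinucleotide steps;
   each step carries one of 96 NtC conformer classes (BB00/BB01 ≈ BI,
   BB07 ≈ BII, AA00 ≈ A, ZZ1S/ZZS1 ≈ Z; unassignable steps are NANT) and a
   2-letter sequence, giving 96 × 16 = 1536 combinations. Waters within
   *d*<sub>assoc</sub> = 4.0 Å of a step are associated with it and
   transferred onto the combination's reference dinucleotide by
   superposing the six step atoms nearest the water. A combination with
   ≥ 800 accumulated waters is considered reliable.
3. **Densities and hydration sites** — the transferred water ensemble is
   smoothed into a 3D probability density (separately for waters within
   3.4 Å of base atoms and of sugar–phosphate atoms); density peaks are
   hydration sites (HS), and the HS **occupancy** is the number of waters
   within 1 Å of the site divided by the number of contributing
   dinucleotides — the expected per-step presence of a water there.
4. **Prediction** — for a target structure, the matching block of each
   step is superposed onto it and all block waters are accumulated into
   two global density grids, each water weighted 1/*n*<sub>steps</sub> of
   its block so populous conformers do not outweigh rare ones. Peaks of
   those grids are the predicted hydration sites; they can be scored by
   the distance to the nearest crystallographic water (asymmetric unit
   plus symmetry mates), binned at 0.5 Å, and summarized as the fraction
   of sites within 1.0 Å.

NtC classification itself is pluggable: supply an externally produced
assignment table, or torsion centroids for the built-in nearest-centroid
approximation over nine backbone/glycosidic torsions.

## Worked example

The synthetic generator builds idealized B-form dinucleotides, scatters
rigid copies and plants hydration sites with known occupancies, so the
whole pipeline can be exercised without downloading any structures:

```sh
watblocks synth --seq2 GC --n-structures 60 --seed 11 --out corpus
ls corpus/*.pdb > structures.txt

# one-centroid classifier table (BB00 = the ideal B-form step's torsions)
python - <<'PY'
from watblocks.fragments import ClassifierTable, step_torsions
from watblocks.synthetic import make_ideal_step
table = ClassifierTable(centroids={"BB00": step_torsions(make_ideal_step("GC", "B")).values})
table.write_centroids("centroids.tsv")
PY
echo '{"association": {"min_waters_reliable": 100}}' > params.json

watblocks build-blocks --structures structures.txt \
    --centroids centroids.tsv --out library --params params.json
watblocks predict --target corpus/syn0000.pdb --library library \
    --centroids centroids.tsv --out pred --evaluate --no-symmetry \
    --params params.json
```

`build-blocks` prints the combination summary:

```
 ntc seq2  n_steps  n_waters  waters_per_step  reliable
BB00   GC       60       135             2.25      True
```

i.e. all 60 corpus dinucleotides were classified BB00/GC and carried 135
associated waters in total. `predict` reports

```
2 base + 2 backbone sites predicted
```

and `pred/evaluation.json` contains the distance histogram against the
target's own waters:

```json
{"frac_within_1A": {"base": 1.0, "backbone": 1.0, "overall": 1.0},
 "histogram": {"overall": [4, 0]}}
```

— all four predicted sites fall within 0.5 Å of an observed water, as
expected when the target is drawn from the same conditions the library
was built from. The output directory also holds `base.ccp4` /
`backbone.ccp4` density maps, `sites.pdb` (pseudo-water records whose
occupancy column is the HS occupancy) and `sites.tsv` / `steps.tsv`
tables, all readable by standard viewers.

The same machinery works on real mmCIF/PDB files with crystallographic
waters and symmetry; see `watblocks curate` for the chain-selection
pipeline on a CSV chain table.

## Layout

- `src/watblocks/structure_io.py` — mmCIF/PDB reading (gemmi), symmetry
  expansion, CCP4/MRC map and hydration-site writers
- `src/watblocks/curation.py` — chain table, clustering, representative
  selection
- `src/watblocks/fragments.py` — dinucleotide steps, base/backbone atom
  partition, torsions, NtC label assignment
- `src/watblocks/blocks.py` — Kabsch superposition, water association and
  transfer, block library persistence
- `src/watblocks/density.py` — Gaussian kernel densities, peak picking,
  occupancies
- `src/watblocks/predict.py` — whole-structure prediction and evaluation
- `src/watblocks/synthetic.py` — idealized DNA builder and corpus
  generator
- `src/watblocks/app.py` — pipeline orchestration and the `watblocks` CLI
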