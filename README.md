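# kcatscreen

Desk-scale toolkit for rational enzyme design by in-silico saturation
mutagenesis: enumerate every single-residue substitution of a protein,
score the mutants with two turnover-number (kcat) predictors, calibrate
and combine the predictions, screen candidates against structure-based
exclusion criteria, pick the best surviving mutation at each locus, and
propose multi-point variants from the winners.

It was built around the engineering of N-carbamoyl-D-amino acid
amidohydrolase (DCase, PDB 1ERZ), the enzyme that hydrolyses
N-carbamoyl-D-p-hydroxyphenylglycine (CpHPG) to the antibiotic precursor
D-HPG, where this workflow surfaced single mutants such as Q4C, T212S
and A302C and the triple mutant Q4C/T212S/A302C. The toolkit is
enzyme-agnostic: it takes a FASTA sequence, a PDB structure, a substrate
SMILES and per-variant kcat tables.

## Method

1. **Saturation scan.** For a sequence of length *L*, enumerate all
   19·*L* substitutions (or restrict to chosen sites). Deep-learning
   kcat predictors are integrated through a TSV contract
   (`variant\tkcat`, with `# predictor_id=`, `# sequence_id=`,
   `# substrate=` sidecar lines); a deterministic hash-based baseline
   predictor is built in so the pipeline runs without GPU models.
2. **Ensemble calibration.** Two predictors K1 and K2 usually disagree
   in scale. The default rule rescales K1 onto K2's scale by the
   wild-type ratio

   ```
   factor = K2(WT) / K1(WT),      combined(v) = K1(v) · factor
   ```

   which preserves K1's ranking exactly and reproduces K2(WT) for the
   wild type (e.g. a wild-type pair of 4.34 and 16.64 s⁻¹ gives
   factor ≈ 3.83). A per-variant geometric mean √(K1·K2) is available as
   an alternative.
3. **Exclusion screen** on the wild-type structure: (i) substitutions
   that lose the chemical class behind a detected salt bridge
   (charged-group heavy atoms ≤ 4.0 Å) or side-chain hydrogen bond
   (donor/acceptor N/O ≤ 3.5 Å); (ii) substitutions whose side-chain
   volume exceeds the free volume in a 5 Å shell around the site's Cβ
   (steric clash); (iii) hydrophobic substitutions at surface sites
   (Shrake–Rupley relative SASA ≥ 0.25). Every threshold is a config
   key and is echoed in output headers.
4. **Ranking and combination.** Per locus, the surviving mutation(s) of
   maximal combined kcat win (exact ties keep all tied mutations); all
   2..k subsets of the winners are proposed as multi-point variants.

## Worked example

```python
import kcatscreen as ks

k1 = ks.PredictionTable("k1", sequence_id="dcase", substrate_smiles="CC(N)C(=O)O")
k1.add("WT", 4.34); k1.add("R3E", 6.02)
k2 = ks.PredictionTable("k2", sequence_id="dcase", substrate_smiles="CC(N)C(=O)O")
k2.add("WT", 16.64)

cal = ks.calibrate(k1, k2)
combined = ks.combine(k1, k2, cal)
print(f"factor = {cal.factor:.3f}")
print(f"combined WT  = {combined['WT']:.2f} s^-1")
print(f"combined R3E = {combined['R3E']:.2f} s^-1")
```

prints

```
factor = 3.834
combined WT  = 16.64 s^-1
combined R3E = 23.08 s^-1
```

i.e. the second predictor's wild-type value is 3.834× the first's, the
combined wild type equals K2(WT) exactly, and the first predictor's
R3E value rescales to 23.08 s⁻¹ — the quantity the per-locus selection
ranks on. The same steps are exposed as CLI subcommands:

```
kcatscreen scan    --fasta enzyme.fasta --substrate "CC(N)C(=O)O" --seed 1 -o k1.tsv
kcatscreen combine --k1 k1.tsv --k2 k2.tsv -o combined.tsv
kcatscreen filter  --pdb enzyme.pdb --mutations muts.txt -o verdicts.tsv
kcatscreen report  --combined combined.tsv --verdicts verdicts.tsv \
                   --tie-break alphabetical --out-dir report/
kcatscreen propose --winners Q4C,T212S,A302C --max-order 3 -o combos.tsv
```

`propose` with the three winners above emits exactly four variants:
`Q4C/T212S`, `Q4C/A302C`, `T212S/A302C`, `Q4C/T212S/A302C`.

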