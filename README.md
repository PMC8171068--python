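# superspacer

Superspace analysis of commensurately modulated crystal structures.

Some protein crystals diffract with strong *main* reflections surrounded by
weaker *satellite* reflections: a periodic distortion (a modulation) breaks
the translational symmetry of the basic unit cell. When the modulation is
commensurate, indexing locks onto a **supercell** of N basic cells and the
deposited model contains N near-copies of the asymmetric unit related by
translational noncrystallographic symmetry (tNCS). The classic examples are
the Hyp-1–ANS complexes: PDB entry 4n3e (a sevenfold supercell, **q** =
(0, 0, 3/7)) and 6sjj (ninefold, **q** = (0, 0, 4/9)).

`superspacer` makes such structures analysable in (3+1)-dimensional
superspace, where the modulation is periodic again. For an atom with average
position **x̄** in basic cell **n**, the superspace coordinate is

    x4 = q · (x̄ + n) = q · x̄ + t,        t = frac(q · n) ∈ [0, 1)

Sorting the N basic cells by fractional x4 (the *superorder*) arranges them
along one period of every atomic modulation function (AMF), turning the
apparently random cell-to-cell differences of the supercell into smooth
sampled waveforms — sinusoids, sawtooths, occupancy windows.

The package provides:

- **q-vector handling** (`superspacer.qvector`) — rationalize a decimal
  **q** to the smallest-denominator fraction within tolerance, count basic
  cells (the product of the denominators), estimate **q** from average
  reflection intensities vs *l*, and reindex supercell reflections into
  superspace labels (h₃, h₄).
- **tNCS diagnostics** (`superspacer.tncs`) — a 1D Patterson section
  P(w) = Σ I(hkl)·cos(2πlw), normalized to the origin, and detection of the
  tNCS repeat 1/N from its non-origin peaks.
- **Supercell partitioning** (`superspacer.partition`) — assign chains to
  basic cells by center of mass, fold all cells onto the first, group
  tNCS-related chains into prime-notation families (B′ = B, D, F, …),
  compute average structures, and produce the superorder with exact rational
  arithmetic.
- **AMF approximations** (`superspacer.amf`) — displacement and occupancy
  series vs t per family and axis, sawtooth-reset location, mirror-pair
  comparison (t → 1 − t), and animation-frame export in superspace order.
- **A ground-truthed synthetic generator** (`superspacer.synthetic`) —
  modulated supercells emulating the two exemplar geometries, plus
  point-scatterer 00l diffraction, so every stage is testable end to end.

## Worked example

Generate the sevenfold exemplar and analyse it:

```sh
superspacer simulate --q 0,0,3/7 --seed 1 --out demo/
superspacer analyze --pdb demo/supercell.pdb --q 0,0,0.428571
```

```
Superspace decomposition
================================================================
q vector:            (0, 0, 3/7)
basic cells:         7 (1 x 1 x 7)
supercell (A):       146.29 146.29 298.55
basic cell (A):      146.29 146.29 42.65
chains:              28
families:            4 (A', B', C', D')

Superspace order (1-based cell index : t)
  1:0  6:1/7  4:2/7  2:3/7  7:4/7  5:5/7  3:6/7
...
Sawtooth resets along x3 (t, jump in fractional units)
  A'     t = 0.3571, jump = 0.01714
  B'     t = 0.3571, jump = 0.01714
  C'     t = 0.0714, jump = 0.01715
  D'     t = 0.6429, jump = 0.01715
```

Reading: the decimal 0.428571 rationalizes to σ₃ = 3/7, so the supercell is
seven basic cells along **x₃** and cell k samples the AMFs at
t = frac(3k/7) — traversed in superspace order 1, 6, 4, 2, 7, 5, 3. The 28
chains fall into four families of seven tNCS copies. Each family's x₃ AMF
is a sawtooth whose reset t and jump match the generator's input.

The diffraction-side diagnostics recover the same picture from intensities
alone:

```sh
superspacer qscan --sf-file demo/reflections.cif      # estimated sigma3 = 3/7
superspacer patterson --sf-file demo/reflections.cif  # tNCS spacing: 1/7
```

The same calls work from Python through the Model/Results interface:

```python
from superspacer import SuperspaceModel, make_sevenfold_example

model, truth = make_sevenfold_example(seed=1)
results = SuperspaceModel(model, (0, 0, 0.428571)).fit()
print(results.summary())
results.export("demo_out/")            # AMF TSVs, superorder table, frames PDB
```

## Limitations

- One modulation wavevector only ((3+1)D); multi-**q** modulations are out
  of scope.
- The deposited chains are taken as the analysis set; crystallographic
  symmetry expansion is not applied.
- AMFs are sample approximations at the N commensurate t values; no
  continuous basis functions are fitted. See `docs/methods.md` for the full
  model description and numerical choices.
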