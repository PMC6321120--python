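# habitkit

Crystal habit prediction and supramolecular geometry analysis for
small-molecule crystal structures.

Given a crystal structure in CIF format (cell parameters, space-group
symmetry, fractional coordinates), `habitkit` answers the questions a
solid-state structure report asks:

* **What shape do the crystals grow?** The growth-morphology (attachment
  energy) model and its geometric BFDH variant, built by half-space
  intersection into a closed convex habit with per-face area percentages.
* **What holds the packing together?** Hydrogen-bond tables with symmetry
  codes, ring perception with centroids (Cg), π–π and T-shaped stacking
  classification with slippage, Cremer–Pople ring puckering.
* **How dense is the packing?** Kitaigorodskii-style packing coefficient and
  a grid/probe search for solvent-accessible voids.
* **How do conformers compare?** Kabsch least-squares superposition and RMSD.

The audience is structural chemists and crystal-engineering researchers who
want these quantities scriptable and testable rather than locked inside GUI
packages.

## The model

Crystal growth bookkeeping follows the periodic-bond-chain picture. For a
face *(hkl)*, the crystallization energy per growth unit (molecule) splits
into the lateral interaction inside one d<sub>hkl</sub>-thick slice and the
interaction with everything outside it:

```
E_cr = E_slice + E_att            (a constant of the structure)
G_r  ∝ E_att                      (growth rate of the face)
```

Fast-growing faces (large |E<sub>att</sub>|) grow themselves out of the
habit; slow faces dominate. The steady-state shape places each face at a
center-to-plane distance proportional to |E<sub>att</sub>|, with the plane
normal along the reciprocal-lattice vector *h*·**a**\* + *k*·**b**\* +
*l*·**c**\*; intersecting all symmetry-equivalent half-spaces gives the
habit polyhedron and the facet-area table. Energies can be computed with
the built-in transferable Lennard-Jones(+Coulomb) potential or supplied
externally (e.g. from a force-field package) as a two-column CSV.

## Worked example

The repository ships the published unit cell of an isoxazolidinyl
pseudouridine nucleoside analogue (monoclinic C2/c, a = 19.9960 Å,
b = 16.7246 Å, c = 19.1703 Å, β = 116.319°) and the four reported
attachment energies of its morphologically important forms:

```sh
habitkit morphology examples/c2c_cell_synthetic.cif \
    --energies-csv examples/gm_face_energies.csv
```

prints

```
 hkl  multiplicity     d_hkl     E_att  tfa_percent
 110             4 12.227874 -214.9592    57.207680
 002             2  8.591548 -208.9238    27.505365
11-1             4 11.788676 -299.1849    12.705832
 111             4  8.786096 -255.0837     2.581123
```

Reading: the {110} prism faces cover 57% of the crystal surface — the habit
is a flat, block-like plate dominated by {110} with a prominent flat (002)
top face, while the fast-growing {11-1} and {111} forms are minor. The
`d_hkl` column is the interplanar spacing from the reciprocal metric tensor
of the cell; `tfa_percent` sums to 100 over all forms.

The same library calls are available in Python:

```python
import habitkit as hk

cell = hk.CellParameters(19.9960, 16.7246, 19.1703, 90, 116.319, 90)
hk.d_spacing(cell, (1, 1, 0))     # 12.2279 Å
hk.cell_volume(cell)              # 5746.5 Å³
```

Other entry points: `habitkit inspect` (cell/symmetry/Z consistency),
`habitkit forms` (growth-form enumeration), `habitkit energies`
(slice/attachment decomposition with the built-in potential),
`habitkit contacts`, `habitkit pucker`, `habitkit voids`, and
`habitkit fixture` for synthetic ground-truth structures.

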