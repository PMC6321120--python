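# Synthetic placeholder structure: the published monoclinic C2/c cell of the
# isoxazolidinyl pseudouridine analogue with a single dummy carbon site.
# Only the cell and symmetry are meaningful; atomic coordinates of the real
# structure are not included.  Pair with gm_face_energies.csv for the
# growth-morphology worked example.
data_c2c_cell_synthetic
_cell_length_a   19.996000
_cell_length_b   16.724600
_cell_length_c   19.170300
_cell_angle_alpha   90.000000
_cell_angle_beta   116.319000
_cell_angle_gamma   90.000000
loop_
_space_group_symop_operation_xyz
  'x,y,z'
  '-x,y,-z+1/2'
  '-x,-y,-z'
  'x,-y,z+1/2'
  'x+1/2,y+1/2,z'
  '-x+1/2,y+1/2,-z+1/2'
  '-x+1/2,-y+1/2,-z'
  'x+1/2,-y+1/2,z+1/2'
loop_
_atom_site_label
_atom_site_type_symbol
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
  C1 C 0.13000000 0.17000000 0.11000000
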