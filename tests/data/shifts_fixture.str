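data_synthetic_uim_fixture

save_assigned_chem_shift_list_1
   _Assigned_chem_shift_list.Sf_category    assigned_chemical_shifts
   _Assigned_chem_shift_list.ID             1

   loop_
      _Atom_chem_shift.ID
      _Atom_chem_shift.Seq_ID
      _Atom_chem_shift.Comp_ID
      _Atom_chem_shift.Atom_ID
      _Atom_chem_shift.Val

       1 336 GLU CA  57.10
       2 336 GLU CB  29.70
       3 336 GLU N  120.90
       4 337 GLU CA  57.60
       5 337 GLU CB  29.50
       6 337 GLU N  120.10
       7 338 ASP CA  54.80
       8 338 ASP CB  40.90
       9 338 ASP N  120.60
      10 339 GLN CA  56.20
      11 339 GLN CB  29.10
      12 339 GLN N  119.50
      13 340 LEU CA  55.70
      14 340 LEU CB  42.20
      15 340 LEU N  121.60
      16 341 ARG CA  56.40
      17 341 ARG CB  30.70
      18 341 ARG N  120.30
   stop_

save_
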