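# Crystal structures

The acceptance targets t2-t6 run on the tethered receptor-ectodomain crystal
structures 1NQL, 3QWQ and 1YY9 (plus 1IVO for reference).  This directory is
expected to hold them as plain-text PDB files named `1nql.pdb`, `3qwq.pdb`,
`1yy9.pdb`.

They are not bundled: the environment in which this repository was built had
no network route to the public structure archive.  With network access, run

    python scripts/fetch_structures.py

to populate this directory; the crystal-structure tests and acceptance
targets then activate automatically.
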