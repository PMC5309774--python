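# Local structure files

Place mmCIF (or PDB) copies of the analysed ribosome entries here to
run the published-value checks and the full dataset pipeline:

    4GD2.cif   open reference (classical state, vacant E site)
    4V9H.cif   P/E hybrid (closed stalk)
    4V90.cif   P/E hybrid (closed stalk)
    4V9K.cif   pe/E chimeric hybrid (intermediate 1)
    4V67.cif   classical E/E (intermediate 2)

e.g. `wget https://files.rcsb.org/download/4GD2.cif`. These files are
large and not redistributable as package fixtures, so they are never
committed; without them the corresponding tests fail with an
explanatory message and everything else runs self-contained.
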