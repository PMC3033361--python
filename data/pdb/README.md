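# Reference structures

Two validation tests compare computed geodesic distances against values
published for deposited structures. They look for the following files in
this directory (lowercase names):

    1mp6.pdb  1g1j.pdb  2k98.pdb  2eow.pdb  1ycc.pdb  1gu2.pdb

PDB entries are redistributable but not bundled here; download them with

    for id in 1MP6 1G1J 2K98 2EOW 1YCC 1GU2; do
        curl -O https://files.rcsb.org/download/$id.pdb
    done

and rename to lowercase. Without the files those two tests fail with a
message pointing here; all other tests are self-contained.
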