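#!/bin/sh
# The same pipeline from the shell: fixtures -> stats/network -> demo.
# Run from anywhere after `pip install -e .`; writes into ./scratch-cli.
set -e
OUT=scratch-cli
atmkit make-fixtures --seed 3 --out "$OUT"
echo "--- benchmark table on the noisy synthetic edge set ---"
atmkit stats --edges "$OUT/edges_noisy.csv" --n-boot 500
echo "--- absolute dG per ligand on the exact edge set ---"
atmkit network --edges "$OUT/edges_exact.csv" --out "$OUT/nodes.csv"
echo "--- closed-form harmonic benchmark, MM and hybrid ---"
atmkit demo --seed 3
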