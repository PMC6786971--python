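"""Write a complete synthetic fixture directory in the on-disk formats.

The fixture contains everything a shell run needs: an assembly FASTA,
per-binner contigs2bin tables, the SCG annotation table, the ground-truth
partition and the reference map for evaluation.  The equivalent CLI call
is `consbin simulate --out-dir fixture --seed 13 --write-fasta`.
"""

import tempfile
from pathlib import Path

from click.testing import CliRunner

from consbin.cli import main

out = Path(tempfile.mkdtemp()) / "fixture"
res = CliRunner().invoke(main, [
    "simulate", "--out-dir", str(out), "--seed", "13",
    "--n-genomes", "6", "--n-binners", "3", "--write-fasta",
])
assert res.exit_code == 0, res.output

for p in sorted(out.iterdir()):
    print(f"{p.name:32s} {p.stat().st_size:>10d} bytes")
print(f"\nFixture written to {out}; feed the binner_* tables, assembly.fasta "
      f"and scg.tsv to `consbin run`, and ref_map.tsv/genomes.tsv to `consbin eval`.")
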