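"""Multiple sequence alignment via the mafft command-line tool.

mafft is the standard progressive aligner for this kind of family-level
work; it is called through a temp-file subprocess and its output is
re-cased/restored so that degapped rows equal the input sequences exactly
(mafft is also asked not to reorder).  Stop symbols ('*') are passed to
mafft as 'X' and restored afterwards.
"""

from __future__ import annotations

import subprocess
import tempfile
from pathlib import Path


class MsaError(RuntimeError):
    pass


def mafft_align(named_seqs: list[tuple[str, str]],
                protein: bool = True) -> list[tuple[str, str]]:
    """Align sequences, preserving input order and original symbols."""
    if not named_seqs:
        return []
    if len(named_seqs) == 1:
        return list(named_seqs)
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "in.fa"
        with open(fasta, "w") as fh:
            for i, (_, seq) in enumerate(named_seqs):
                fh.write(f">s{i}\n{seq.upper().replace('*', 'X')}\n")
        cmd = ["mafft", "--quiet", "--auto", "--anysymbol"]
        cmd += ["--amino"] if protein else ["--nuc"]
        cmd.append(str(fasta))
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise MsaError(f"mafft failed: {proc.stderr.strip()[:500]}")
    aligned: dict[str, str] = {}
    cur = None
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            cur = line[1:].strip()
            aligned[cur] = ""
        elif cur is not None:
            aligned[cur] += line.strip()
    out = []
    for i, (name, seq) in enumerate(named_seqs):
        row = aligned[f"s{i}"]
        restored = []
        j = 0
        for ch in row:
            if ch == "-":
                restored.append("-")
            else:
                restored.append(seq[j])
                j += 1
        if j != len(seq):
            raise MsaError(f"mafft row for {name} does not degap to its input")
        out.append((name, "".join(restored)))
    return out
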