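"""One-off generator for the packaged synthetic hallmark fixture FASTA.

Run from the repository root:

    python scripts/make_hallmark_fixtures.py

Writes src/hybridsip/data/hallmarks_synthetic.faa. The output is committed;
this script exists to document exactly how the fixtures were produced. The
proteins are random draws from background amino-acid frequencies (Robinson &
Robinson 1991) with a fixed seed — synthetic surrogates, not homologues of
any real hallmark gene family.
"""

from __future__ import annotations

import pathlib

import numpy as np

SEED = 740_113
LENGTH_RANGE = (150, 400)  # aa, excluding the leading Met

# Robinson & Robinson (1991) background amino-acid frequencies.
AA = "ACDEFGHIKLMNPQRSTVWY"
FREQ = np.array([
    0.078, 0.019, 0.054, 0.063, 0.039, 0.074, 0.022, 0.052, 0.057, 0.090,
    0.022, 0.045, 0.052, 0.043, 0.051, 0.071, 0.058, 0.064, 0.013, 0.032,
])
FREQ = FREQ / FREQ.sum()

# Guild annotation per kind: the AOA-specific MCO1 has AOA entries only.
# Enough AOA entries that every cassette-bearing genome in the default
# two-soil scenario receives its own query (no two genomes share identical
# back-coded cassette DNA, which would cross-recruit reads).
GUILD_PLAN = {
    "capsid": ["AOA"] * 16 + ["AOB"] * 2 + ["NOB"] * 2,
    "terminase": ["AOA"] * 16 + ["AOB"] * 2 + ["NOB"] * 2,
    "portal": ["AOA"] * 16 + ["AOB"] * 2 + ["NOB"] * 2,
    "integrase": ["AOA"] * 16 + ["AOB"] * 2 + ["NOB"] * 2,
    "mco1": ["AOA"] * 12,
}


def main() -> None:
    rng = np.random.default_rng(SEED)
    out = pathlib.Path("src/hybridsip/data/hallmarks_synthetic.faa")
    lines: list[str] = []
    aa = np.array(list(AA))
    for kind, guilds in GUILD_PLAN.items():
        for i, guild in enumerate(guilds, start=1):
            n = int(rng.integers(LENGTH_RANGE[0], LENGTH_RANGE[1] + 1))
            body = "".join(rng.choice(aa, size=n - 1, p=FREQ))
            seq = "M" + body
            lines.append(f">{kind}_{guild}_{i:02d} kind={kind} guild={guild} synthetic=true")
            lines.extend(seq[j : j + 60] for j in range(0, len(seq), 60))
    out.write_text("\n".join(lines) + "\n")
    print(f"wrote {out} ({sum(len(g) for g in GUILD_PLAN.values())} records)")


if __name__ == "__main__":
    main()
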