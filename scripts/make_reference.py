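"""One-off generator for the packaged synthetic IGH mini-locus (frozen seed).

Regenerates src/bcrep/data/igh_mini_synthetic.{fasta,_anchors.tsv} exactly.
Run from the repository root: python scripts/make_reference.py
"""
import numpy as np

rng = np.random.default_rng(20260922)
NT = np.array(list("ACGT"))
STOPS = {"TAA", "TAG", "TGA"}


def rand_nt(n):
    return "".join(rng.choice(NT, size=n))


def codon_ok(c):
    return c not in STOPS


v_names = ["IGHV1-7*01", "IGHV1-26*01", "IGHV1-82*01", "IGHV2-2*01",
           "IGHV3-6*01", "IGHV5-17*01", "IGHV6-3*01", "IGHV9-3*01"]
d_names = ["IGHD1-1*01", "IGHD2-3*01", "IGHD3-1*01", "IGHD4-1*01"]
j_names = ["IGHJ1*01", "IGHJ2*01", "IGHJ3*01", "IGHJ4*01"]

records = []
anchors = []

for name in v_names:
    L = int(rng.integers(291, 301))
    # anchor = L-9: Cys codon followed by two non-stop codons inside CDR3
    body = rand_nt(L - 9)
    while True:
        tail = [rand_nt(3), rand_nt(3)]
        if all(codon_ok(c) for c in tail):
            break
    seq = body + "TGT" + "".join(tail)
    assert len(seq) == L
    fam = name.split("*")[0].split("-")[0]
    records.append((name, "V", fam, seq))
    anchors.append((name, "V", L - 9))

for name in d_names:
    L = int(rng.integers(10, 18))
    fam = name.split("*")[0].split("-")[0]
    records.append((name, "D", fam, rand_nt(L)))

for i, name in enumerate(j_names):
    L = int(rng.integers(48, 54))
    a = int(rng.integers(9, 13))
    codon = "TTT" if i == 2 else "TGG"  # one Phe anchor, rest Trp
    seq = rand_nt(a) + codon + rand_nt(L - a - 3)
    fam = name.split("*")[0]
    records.append((name, "J", fam, seq))
    anchors.append((name, "J", a))

with open("src/bcrep/data/igh_mini_synthetic.fasta", "w") as fh:
    for name, cls, fam, seq in records:
        fh.write(f">{name}|{cls}|{fam}\n")
        for i in range(0, len(seq), 60):
            fh.write(seq[i:i + 60] + "\n")

with open("src/bcrep/data/igh_mini_synthetic_anchors.tsv", "w") as fh:
    fh.write("name\tclass\tanchor\n")
    for name, cls, a in anchors:
        fh.write(f"{name}\t{cls}\t{a}\n")

print("wrote", len(records), "segments")
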