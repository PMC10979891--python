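"""Full offline pipeline on generated inputs with a planted insertion site.

Creates a complete toy input set (query FASTA, MSA, DSSP file, structure,
disordered-binding track) engineered so that one window of residues is
simultaneously variable, coil, exposed and free of predicted binding
regions, then runs the scoring pipeline and prints the ranked sites.
"""

import tempfile

from tagsite import make_fixture, run_pipeline

bundle = make_fixture(tempfile.mkdtemp(), length=60, peak_position=30, seed=1)
result = run_pipeline(
    bundle.query_fasta,
    bundle.msa_fasta,
    bundle.anchor,
    dssp_file=bundle.dssp,
)

print(f"query: {bundle.query_id}, {len(bundle.sequence)} residues")
print(f"planted favorable window: positions {bundle.window_positions}")
print()
print("rank  pos  res  smoothed-min  entropy  ss   rsa   1-BR")
for site in result.sites:
    h, ss, rsa, dbr = site.feature_values
    print(
        f"{site.rank:>4}  {site.position:>3}  {site.residue}    "
        f"{site.score:.4f}        {h:.3f}    {ss:.1f}  {rsa:.2f}  {dbr:.2f}"
    )

print()
top = result.sites[0]
print(
    f"The rank-1 site is position {top.position} — the planted peak. Its "
    f"score {top.score:.4f} is the window-7 average of the per-position "
    "minimum feature; inside the planted window that minimum is the "
    "normalized entropy 3/log2(20) = 0.6941, and it is ~0 everywhere else."
)
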