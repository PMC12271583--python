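"""Apply the dataset-inclusion rules to a candidate metadata table.

Keeps entries that have a biological assembly, an FSC-0.143 resolution
inside the 1-4 Å window, and are the best-resolution representative of
their assembly; every rejection names the rule that fired.
"""

import cryolabel as cl

candidates = [
    cl.MapRecord("EMD-11900", "7asm", 1.8),
    cl.MapRecord("EMD-23075", "7kyc", 2.4),
    cl.MapRecord("EMD-90001", None, 2.0),                          # no assembly
    cl.MapRecord("EMD-90002", "9zzz", None),                       # no FSC-0.143 value
    cl.MapRecord("EMD-90003", "9yyy", 5.2),                        # outside 1-4 Å
    cl.MapRecord("EMD-90004", "7kyc", 3.0),                        # redundant, worse
]

kept, reasons = cl.curate(candidates, res_min=1.0, res_max=4.0)

print("kept:")
for r in kept:
    print(f"  {r.emdb_id}  {r.pdb_id}  {r.resolution} Å")
print("rejected:")
for emdb, why in sorted(reasons.items()):
    print(f"  {emdb}: {why}")

# One representative per assembly survives (the lowest-resolution EMDB entry
# is kept per pdb_id); the rejection column is what the curated CSV carries.
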