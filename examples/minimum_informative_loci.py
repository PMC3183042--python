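"""How many introgressed autosomal loci make sex bias significant?

Scans the number of short-branch (introgressed) autosomal loci combined
with one long-branch Y locus, and separately the number of long-branch
autosomal loci combined with one short mitochondrial locus.
"""

from sexmig import Branch, MarkerClass, ObservedPattern, min_loci_to_reject

base_y = ObservedPattern.from_counts([("Y", "long", 1)])
res = min_loci_to_reject(base_y, (MarkerClass.AUTOSOME, Branch.SHORT), max_n=20)
print("long Y + k short autosomal loci:")
for k, lr in enumerate(res.lr_trajectory, start=1):
    print(f"  k={k:2d}  LR = {lr:.3f}")
print(f"  smallest k rejecting at 5%: {res}")
print()

base_mt = ObservedPattern.from_counts([("MT", "short", 1)])
res2 = min_loci_to_reject(base_mt, (MarkerClass.AUTOSOME, Branch.LONG), max_n=100)
print(f"short mito + n long autosomal loci: smallest rejecting n = {res2}")
print()
print("Five introgressed autosomes against a non-introgressed Y suffice to")
print("reject sexually equal migration, but exclusive mitochondrial")
print("introgression stays compatible with equal rates even against 100")
print("non-introgressed autosomes: high female migration would have")
print("intermingled the autosomes too, so the autosomal long branches cap")
print("the migration rate rather than implicating either sex.")
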