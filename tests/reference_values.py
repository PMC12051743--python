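"""Published genome-wide vQTL summary statistics for BMI in an admixed
discovery cohort (n = 22,805) with replication in a continental African
cohort (n = 6,002), used as worked-example inputs.

Each row: (site_id, chrom, discovery p, discovery r2_adj, replication p,
replication r2_adj).  The 15 markers form eight loci by distance/LD
clumping; replication at marker-level p < 0.05 yields six markers in the
three loci on chromosomes 2, 6 and 7.
"""

N_DISCOVERY = 22805
N_REPLICATION = 6002

TABLE = [
    ("chr2:164648055:G:T",   "2",  3.68e-08, 1.28e-03, 0.03410188,  5.82e-04),
    ("chr2:164655284:C:G",   "2",  2.56e-08, 1.32e-03, 0.02385151,  6.84e-04),
    ("chr2:164668241:C:G",   "2",  1.73e-08, 1.35e-03, 0.01431195,  8.33e-04),
    ("chr2:164669828:T:C",   "2",  1.49e-08, 1.36e-03, 0.01687543,  7.85e-04),
    ("chr2:164687940:G:A",   "2",  1.26e-08, 1.38e-03, 0.0650255,   4.01e-04),
    ("chr2:164688863:C:CAA", "2",  3.77e-08, 1.28e-03, 0.2937594,   1.71e-05),
    ("chr3:78354830:C:T",    "3",  1.65e-08, 1.35e-03, 0.3790635,  -3.87e-05),
    ("chr6:85227974:C:T",    "6",  3.95e-11, 1.87e-03, 0.0311676,   6.07e-04),
    ("chr7:76211003:A:G",    "7",  2.46e-08, 1.32e-03, 0.02781348,  6.40e-04),
    ("chr10:99498312:C:G",   "10", 3.40e-08, 1.29e-03, 0.6434473,  -1.31e-04),
    ("chr12:64004860:C:T",   "12", 1.22e-08, 1.38e-03, 0.8217791,  -1.58e-04),
    ("chr13:19105986:G:A",   "13", 9.88e-09, 1.40e-03, 0.833989,   -1.59e-04),
    ("chr13:105972955:T:G",  "13", 4.93e-08, 1.26e-03, 0.3690827,  -3.22e-05),
    ("chr13:105973696:A:C",  "13", 4.82e-08, 1.26e-03, 0.3679336,  -3.15e-05),
    ("chr13:105973780:A:AT", "13", 4.98e-08, 1.26e-03, 0.3618914,  -2.81e-05),
]

# the eight loci, as lead site id -> member site ids
LOCI = {
    "chr2:164687940:G:A": [r[0] for r in TABLE[:6]],
    "chr3:78354830:C:T": ["chr3:78354830:C:T"],
    "chr6:85227974:C:T": ["chr6:85227974:C:T"],
    "chr7:76211003:A:G": ["chr7:76211003:A:G"],
    "chr10:99498312:C:G": ["chr10:99498312:C:G"],
    "chr12:64004860:C:T": ["chr12:64004860:C:T"],
    "chr13:19105986:G:A": ["chr13:19105986:G:A"],
    "chr13:105972955:T:G": [r[0] for r in TABLE[12:15]],
}
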