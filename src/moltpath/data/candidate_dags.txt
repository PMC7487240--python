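# Candidate causal hypotheses relating migration distance, day length,
# foraging stratum, prealternate molt extent and seasonal dichromatism.
#
# This set is a RECONSTRUCTION, not a verbatim copy: the published analysis
# compared 12 candidate path models but fully describes only three.  The
# constraints it does state are honored exactly: every model makes migration
# distance a direct parent of day length; the two favored models (m2, m3)
# both make molt and foraging stratum direct parents of seasonal
# dichromatism and differ only in whether migration distance or day length
# is the direct parent of prealternate molt; m5 is the best model proposing
# a conditional independency between molt and dichromatism (a direct
# migration effect replaces the molt effect).  The remaining models follow
# the same pattern of separate either/or hypotheses about direct versus
# indirect effects: each crosses one molt parent (migration or day length)
# with one hypothesis about the drivers of dichromatism (molt, migration,
# day length, stratum alone, or no stratum effect); no model nests another
# by a single extra edge.  Edit freely; the pipeline treats this file as
# data.

id: m1
migration -> daylength
migration -> molt
molt -> dichromatism

id: m2
migration -> daylength
migration -> molt
molt -> dichromatism
stratum -> dichromatism

id: m3
migration -> daylength
daylength -> molt
molt -> dichromatism
stratum -> dichromatism

id: m4
migration -> daylength
daylength -> molt
molt -> dichromatism

id: m5
migration -> daylength
daylength -> molt
migration -> dichromatism
stratum -> dichromatism

id: m6
migration -> daylength
migration -> molt
migration -> dichromatism
stratum -> dichromatism

id: m7
migration -> daylength
daylength -> molt
daylength -> dichromatism
stratum -> dichromatism

id: m8
migration -> daylength
migration -> molt
daylength -> dichromatism
stratum -> dichromatism

id: m9
migration -> daylength
migration -> molt
stratum -> dichromatism

id: m10
migration -> daylength
daylength -> molt
stratum -> dichromatism

id: m11
migration -> daylength
migration -> molt
migration -> dichromatism

id: m12
migration -> daylength
daylength -> molt
daylength -> dichromatism
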