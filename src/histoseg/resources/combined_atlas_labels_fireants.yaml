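# Default grouping of atlas ROIs into 16 tissue classes for intensity
# modeling.  Each key is a tissue class; the value lists the atlas label ids
# assigned to it.  The shipped lists are empty because the label ids depend
# on the atlas in use: tools and tests populate them for their atlas (the
# phantom writes its own version of this file).
cerebral white matter: []
cerebral gray matter: []
cerebellar white matter: []
cerebellar cortex: []
caudate: []
putamen: []
pallidum: []
lateral thalamus: []
medial thalamus: []
red nucleus: []
compact brainstem white matter: []
diffuse brainstem white matter: []
hypothalamus: []
mammillary bodies: []
dentate nucleus of the cerebellum: []
hippocampal white matter: []
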