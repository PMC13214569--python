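# Number of Gaussian components per tissue class.  Cerebral gray matter gets
# two components to absorb its broader intensity spread (partial volume with
# sulcal boundaries); all other classes are well described by one.
cerebral white matter: 1
cerebral gray matter: 2
cerebellar white matter: 1
cerebellar cortex: 1
caudate: 1
putamen: 1
pallidum: 1
lateral thalamus: 1
medial thalamus: 1
red nucleus: 1
compact brainstem white matter: 1
diffuse brainstem white matter: 1
hypothalamus: 1
mammillary bodies: 1
dentate nucleus of the cerebellum: 1
hippocampal white matter: 1
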