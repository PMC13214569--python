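# Heuristic intensity rules for the synthetic anatomical volume.  Each class
# mean is a linear combination of robust (median) statistics of the seven
# coarse-protocol reference structures that are reliably segmented in any
# contrast: cerebral white matter, cerebral gray matter, cerebellar white
# matter, cerebellar gray matter, brainstem, thalamus, pallidum.  Mixture
# weights encode typical relative contrast of each class (e.g. thalamus
# intensity sits between gray and white matter on most sequences).
cerebral white matter:
  cerebral white matter: 1.0
cerebral gray matter:
  cerebral gray matter: 1.0
cerebellar white matter:
  cerebellar white matter: 1.0
cerebellar cortex:
  cerebellar gray matter: 1.0
caudate:
  cerebral gray matter: 1.0
putamen:
  cerebral gray matter: 0.8
  cerebral white matter: 0.2
pallidum:
  pallidum: 1.0
lateral thalamus:
  thalamus: 0.5
  cerebral white matter: 0.5
medial thalamus:
  thalamus: 0.85
  cerebral gray matter: 0.15
red nucleus:
  pallidum: 0.5
  thalamus: 0.5
compact brainstem white matter:
  cerebral white matter: 0.8
  brainstem: 0.2
diffuse brainstem white matter:
  brainstem: 1.0
hypothalamus:
  cerebral gray matter: 0.7
  cerebral white matter: 0.3
mammillary bodies:
  cerebral white matter: 0.6
  cerebral gray matter: 0.4
dentate nucleus of the cerebellum:
  cerebellar white matter: 0.5
  cerebellar gray matter: 0.5
hippocampal white matter:
  cerebral white matter: 0.7
  cerebral gray matter: 0.3
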