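# ROI constraints isolating the eight study tracts from a whole-brain
# tractogram. Placements are anatomical rules resolved against named
# landmark masks; anterior-posterior is world +y (RAS+).
# gCC/bCC are midline; the other six are bilateral (14 instances per subject).
tracts:
  - tract: gCC
    laterality: midline
    gates:
      - polarity: AND
        plane: sagittal
        placement: {type: fraction, structure: corpus_callosum, axis: y, from_edge: anterior, lo: 0, hi: 1/6}
        extent: {mode: structure}
        note: anterior 1/6 of the length of the corpus callosum (genu)
      - polarity: NOT
        plane: parasagittal
        side: both
        placement: {type: lateral_edge_slice, structure: corticospinal_tract, offset_mm: 2.7}
        extent: {mode: entire}
        note: slices lateral to the corticospinal tract bilaterally, entire slice

  - tract: bCC
    laterality: midline
    gates:
      # splenium = posterior 1/4; the body is 1/6 to 3/4 measured from anterior
      - polarity: AND
        plane: sagittal
        placement: {type: fraction, structure: corpus_callosum, axis: y, from_edge: anterior, lo: 1/6, hi: 3/4}
        extent: {mode: structure}
        note: corpus callosum excluding genu (anterior 1/6) and splenium (posterior 1/4)
      - polarity: NOT
        plane: axial
        placement: {type: edge_slice, structure: corpus_callosum, edge: inferior, offset_mm: 2.7}
        extent: {mode: entire}
        note: slice just beneath the body of the corpus callosum, entire slice

  - tract: ATR
    laterality: bilateral
    gates:
      - polarity: AND
        plane: coronal
        placement: {type: fraction, structure: corpus_callosum, axis: y, from_edge: anterior, lo: 1/12, hi: 1/12}
        extent: {mode: entire}
        note: slice at the middle of the genu (anterior limb of internal capsule)
      - polarity: AND
        plane: coronal
        placement: {type: edge_slice, structure: pons, edge: anterior}
        extent: {mode: structure, structure: thalamus}
        note: slice at the anterior edge of the pons, defining the thalamus
      - polarity: NOT
        plane: sagittal
        placement: {type: midsagittal}
        extent: {mode: entire}
        note: entire central slice
      - polarity: NOT
        plane: coronal
        placement: {type: edge_slice, structure: thalamus, edge: posterior}
        extent: {mode: entire}
        note: slice at the posterior thalamic edge, entire slice

  - tract: IFO
    laterality: bilateral
    gates:
      - polarity: AND
        plane: coronal
        placement: {type: edge_slice, structure: corpus_callosum, edge: anterior}
        extent: {mode: entire}
        note: slice at the anterior edge of the genu, entire slice
      - polarity: AND
        plane: coronal
        placement: {type: center_slice, structure: parieto_occipital_sulcus}
        extent: {mode: structure, structure: occipital_lobe}
        note: slice at the halfway mark of the parieto-occipital sulcus, occipital lobe
      - polarity: NOT
        plane: sagittal
        placement: {type: midsagittal}
        extent: {mode: entire}
        note: entire central slice

  - tract: ILF
    laterality: bilateral
    gates:
      - polarity: AND
        plane: coronal
        placement: {type: edge_slice, structure: cingulum, edge: posterior}
        extent: {mode: structure, structure: occipital_lobe}
        note: slice at the posterior edge of the cingulum, occipital lobe
      - polarity: AND
        plane: coronal
        placement: {type: fraction, structure: temporal_lobe, axis: y, from_edge: anterior, lo: 0, hi: 0.15}
        extent: {mode: structure}
        note: most posterior slice where temporal and frontal lobes separate, anterior temporal lobe
      - polarity: NOT
        plane: coronal
        placement: {type: fraction, structure: temporal_lobe, axis: y, from_edge: anterior, lo: 0, hi: 0.15}
        extent: {mode: complement}
        note: same slice, rest of the brain except the anterior temporal lobe
      - polarity: NOT
        plane: sagittal
        placement: {type: midsagittal}
        extent: {mode: entire}
        note: entire central slice

  - tract: PLIC
    laterality: bilateral
    gates:
      - polarity: AND
        plane: axial
        placement: {type: max_area_slice, structure: plic}
        extent: {mode: structure}
        note: slice where the PLIC is visibly the largest
      - polarity: AND
        plane: axial
        placement: {type: edge_slice, structure: plic, edge: inferior}
        extent: {mode: structure}
        note: most inferior slice where the PLIC is still visible
      - polarity: NOT
        plane: axial
        placement: {type: center_slice, structure: brainstem}
        extent: {mode: entire}
        note: slice at the condensed corticospinal tract in the brainstem, entire slice

  - tract: PTR
    laterality: bilateral
    gates:
      - polarity: AND
        plane: coronal
        placement: {type: edge_slice, structure: cingulum, edge: posterior}
        extent: {mode: entire}
        note: slice at the posterior edge of the cingulum (periventricular A-P tracts)
      - polarity: AND
        plane: parasagittal
        side: instance
        placement: {type: lateral_edge_slice, structure: thalamus}
        extent: {mode: structure, structure: thalamus}
        note: slice at the lateral edge of the thalamus, defining the thalamus
      - polarity: NOT
        plane: coronal
        placement: {type: edge_slice, structure: thalamus, edge: anterior}
        extent: {mode: entire}
        note: slice at the anterior edge of the thalamus, entire slice
      - polarity: NOT
        plane: axial
        placement: {type: edge_slice, structure: thalamus, edge: inferior}
        extent: {mode: entire}
        note: slice at the inferior edge of the thalamus, entire slice

  - tract: UF
    laterality: bilateral
    gates:
      - polarity: AND
        plane: axial
        placement: {type: center_slice, structure: temporal_lobe}
        extent: {mode: structure}
        note: slice where cephalic-caudal fibres are distinct in the temporal lobe
      - polarity: AND
        plane: coronal
        placement: {type: edge_slice, structure: frontal_lobe, edge: posterior}
        extent: {mode: structure}
        note: slice anterior to the cephalic-caudal fibres, inferior frontal lobe
      - polarity: AND
        plane: coronal
        placement: {type: edge_slice, structure: frontal_lobe, edge: posterior}
        extent: {mode: structure, structure: temporal_lobe}
        note: same slice, temporal lobe
      - polarity: NOT
        plane: coronal
        placement: {type: center_slice, structure: temporal_lobe, offset_mm: -10}
        extent: {mode: entire}
        note: slice posterior to the cephalic-caudal fibres, entire slice
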