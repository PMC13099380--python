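# Default 105-region atlas: 63 cortical, 24 subcortical, 18 amygdala subnuclei.
# FreeSurfer-style names (DKT cortical labels, aseg subcortical, segmentHA subnuclei).
regions:
- {name: ctx-lh-caudalanteriorcingulate, class: cortical, hemisphere: left}
- {name: ctx-lh-caudalmiddlefrontal, class: cortical, hemisphere: left}
- {name: ctx-lh-cuneus, class: cortical, hemisphere: left}
- {name: ctx-lh-entorhinal, class: cortical, hemisphere: left}
- {name: ctx-lh-fusiform, class: cortical, hemisphere: left}
- {name: ctx-lh-inferiorparietal, class: cortical, hemisphere: left}
- {name: ctx-lh-inferiortemporal, class: cortical, hemisphere: left}
- {name: ctx-lh-isthmuscingulate, class: cortical, hemisphere: left}
- {name: ctx-lh-lateraloccipital, class: cortical, hemisphere: left}
- {name: ctx-lh-lateralorbitofrontal, class: cortical, hemisphere: left}
- {name: ctx-lh-lingual, class: cortical, hemisphere: left}
- {name: ctx-lh-medialorbitofrontal, class: cortical, hemisphere: left}
- {name: ctx-lh-middletemporal, class: cortical, hemisphere: left}
- {name: ctx-lh-parahippocampal, class: cortical, hemisphere: left}
- {name: ctx-lh-paracentral, class: cortical, hemisphere: left}
- {name: ctx-lh-parsopercularis, class: cortical, hemisphere: left}
- {name: ctx-lh-parsorbitalis, class: cortical, hemisphere: left}
- {name: ctx-lh-parstriangularis, class: cortical, hemisphere: left}
- {name: ctx-lh-pericalcarine, class: cortical, hemisphere: left}
- {name: ctx-lh-postcentral, class: cortical, hemisphere: left}
- {name: ctx-lh-posteriorcingulate, class: cortical, hemisphere: left}
- {name: ctx-lh-precentral, class: cortical, hemisphere: left}
- {name: ctx-lh-precuneus, class: cortical, hemisphere: left}
- {name: ctx-lh-rostralanteriorcingulate, class: cortical, hemisphere: left}
- {name: ctx-lh-rostralmiddlefrontal, class: cortical, hemisphere: left}
- {name: ctx-lh-superiorfrontal, class: cortical, hemisphere: left}
- {name: ctx-lh-superiorparietal, class: cortical, hemisphere: left}
- {name: ctx-lh-superiortemporal, class: cortical, hemisphere: left}
- {name: ctx-lh-supramarginal, class: cortical, hemisphere: left}
- {name: ctx-lh-transversetemporal, class: cortical, hemisphere: left}
- {name: ctx-lh-insula, class: cortical, hemisphere: left}
- {name: ctx-rh-caudalanteriorcingulate, class: cortical, hemisphere: right}
- {name: ctx-rh-caudalmiddlefrontal, class: cortical, hemisphere: right}
- {name: ctx-rh-cuneus, class: cortical, hemisphere: right}
- {name: ctx-rh-entorhinal, class: cortical, hemisphere: right}
- {name: ctx-rh-fusiform, class: cortical, hemisphere: right}
- {name: ctx-rh-inferiorparietal, class: cortical, hemisphere: right}
- {name: ctx-rh-inferiortemporal, class: cortical, hemisphere: right}
- {name: ctx-rh-isthmuscingulate, class: cortical, hemisphere: right}
- {name: ctx-rh-lateraloccipital, class: cortical, hemisphere: right}
- {name: ctx-rh-lateralorbitofrontal, class: cortical, hemisphere: right}
- {name: ctx-rh-lingual, class: cortical, hemisphere: right}
- {name: ctx-rh-medialorbitofrontal, class: cortical, hemisphere: right}
- {name: ctx-rh-middletemporal, class: cortical, hemisphere: right}
- {name: ctx-rh-parahippocampal, class: cortical, hemisphere: right}
- {name: ctx-rh-paracentral, class: cortical, hemisphere: right}
- {name: ctx-rh-parsopercularis, class: cortical, hemisphere: right}
- {name: ctx-rh-parsorbitalis, class: cortical, hemisphere: right}
- {name: ctx-rh-parstriangularis, class: cortical, hemisphere: right}
- {name: ctx-rh-pericalcarine, class: cortical, hemisphere: right}
- {name: ctx-rh-postcentral, class: cortical, hemisphere: right}
- {name: ctx-rh-posteriorcingulate, class: cortical, hemisphere: right}
- {name: ctx-rh-precentral, class: cortical, hemisphere: right}
- {name: ctx-rh-precuneus, class: cortical, hemisphere: right}
- {name: ctx-rh-rostralanteriorcingulate, class: cortical, hemisphere: right}
- {name: ctx-rh-rostralmiddlefrontal, class: cortical, hemisphere: right}
- {name: ctx-rh-superiorfrontal, class: cortical, hemisphere: right}
- {name: ctx-rh-superiorparietal, class: cortical, hemisphere: right}
- {name: ctx-rh-superiortemporal, class: cortical, hemisphere: right}
- {name: ctx-rh-supramarginal, class: cortical, hemisphere: right}
- {name: ctx-rh-transversetemporal, class: cortical, hemisphere: right}
- {name: ctx-rh-insula, class: cortical, hemisphere: right}
- {name: ctx-lh-temporalpole, class: cortical, hemisphere: left}
- {name: Left-Thalamus-Proper, class: subcortical, hemisphere: left}
- {name: Left-Caudate, class: subcortical, hemisphere: left}
- {name: Left-Putamen, class: subcortical, hemisphere: left}
- {name: Left-Pallidum, class: subcortical, hemisphere: left}
- {name: Left-Hippocampus, class: subcortical, hemisphere: left}
- {name: Left-Amygdala, class: subcortical, hemisphere: left}
- {name: Left-Accumbens-area, class: subcortical, hemisphere: left}
- {name: Left-VentralDC, class: subcortical, hemisphere: left}
- {name: Left-Cerebellum-Cortex, class: subcortical, hemisphere: left}
- {name: Left-Cerebellum-White-Matter, class: subcortical, hemisphere: left}
- {name: Left-Choroid-Plexus, class: subcortical, hemisphere: left}
- {name: Right-Thalamus-Proper, class: subcortical, hemisphere: right}
- {name: Right-Caudate, class: subcortical, hemisphere: right}
- {name: Right-Putamen, class: subcortical, hemisphere: right}
- {name: Right-Pallidum, class: subcortical, hemisphere: right}
- {name: Right-Hippocampus, class: subcortical, hemisphere: right}
- {name: Right-Amygdala, class: subcortical, hemisphere: right}
- {name: Right-Accumbens-area, class: subcortical, hemisphere: right}
- {name: Right-VentralDC, class: subcortical, hemisphere: right}
- {name: Right-Cerebellum-Cortex, class: subcortical, hemisphere: right}
- {name: Right-Cerebellum-White-Matter, class: subcortical, hemisphere: right}
- {name: Right-Choroid-Plexus, class: subcortical, hemisphere: right}
- {name: Brain-Stem, class: subcortical, hemisphere: midline}
- {name: Optic-Chiasm, class: subcortical, hemisphere: midline}
- {name: Left-Lateral-nucleus, class: amygdala_subnucleus, hemisphere: left}
- {name: Left-Basal-nucleus, class: amygdala_subnucleus, hemisphere: left}
- {name: Left-Accessory-Basal-nucleus, class: amygdala_subnucleus, hemisphere: left}
- {name: Left-Anterior-amygdaloid-area-AAA, class: amygdala_subnucleus, hemisphere: left}
- {name: Left-Central-nucleus, class: amygdala_subnucleus, hemisphere: left}
- {name: Left-Medial-nucleus, class: amygdala_subnucleus, hemisphere: left}
- {name: Left-Cortical-nucleus, class: amygdala_subnucleus, hemisphere: left}
- {name: Left-Corticoamygdaloid-transitio, class: amygdala_subnucleus, hemisphere: left}
- {name: Left-Paralaminar-nucleus, class: amygdala_subnucleus, hemisphere: left}
- {name: Right-Lateral-nucleus, class: amygdala_subnucleus, hemisphere: right}
- {name: Right-Basal-nucleus, class: amygdala_subnucleus, hemisphere: right}
- {name: Right-Accessory-Basal-nucleus, class: amygdala_subnucleus, hemisphere: right}
- {name: Right-Anterior-amygdaloid-area-AAA, class: amygdala_subnucleus, hemisphere: right}
- {name: Right-Central-nucleus, class: amygdala_subnucleus, hemisphere: right}
- {name: Right-Medial-nucleus, class: amygdala_subnucleus, hemisphere: right}
- {name: Right-Cortical-nucleus, class: amygdala_subnucleus, hemisphere: right}
- {name: Right-Corticoamygdaloid-transitio, class: amygdala_subnucleus, hemisphere: right}
- {name: Right-Paralaminar-nucleus, class: amygdala_subnucleus, hemisphere: right}
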