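region,hemisphere,lobe,ref_mean,ref_sd
Entorhinal area,left,mesial temporal,0.0012,0.000144
Entorhinal area,right,mesial temporal,0.0012,0.000144
Parahippocampal gyrus,left,mesial temporal,0.0021,0.000252
Parahippocampal gyrus,right,mesial temporal,0.0021,0.000252
Hippocampus,left,mesial temporal,0.0024,0.000288
Hippocampus,right,mesial temporal,0.0024,0.000288
Amygdala,left,mesial temporal,0.0008,9.6e-05
Amygdala,right,mesial temporal,0.0008,9.6e-05
Superior temporal gyrus,left,other temporal,0.0046,0.000552
Superior temporal gyrus,right,other temporal,0.0046,0.000552
Middle temporal gyrus,left,other temporal,0.0087,0.001044
Middle temporal gyrus,right,other temporal,0.0087,0.001044
Inferior temporal gyrus,left,other temporal,0.0071,0.000852
Inferior temporal gyrus,right,other temporal,0.0071,0.000852
Fusiform gyrus,left,other temporal,0.0047,0.000564
Fusiform gyrus,right,other temporal,0.0047,0.000564
Temporal pole,left,other temporal,0.0055,0.00066
Temporal pole,right,other temporal,0.0055,0.00066
Planum temporale,left,other temporal,0.0013,0.000156
Planum temporale,right,other temporal,0.0013,0.000156
Planum polare,left,other temporal,0.0012,0.000144
Planum polare,right,other temporal,0.0012,0.000144
Transverse temporal gyrus,left,other temporal,0.0009,0.000108
Transverse temporal gyrus,right,other temporal,0.0009,0.000108
Superior frontal gyrus,left,frontal,0.009,0.00108
Superior frontal gyrus,right,frontal,0.009,0.00108
Superior frontal gyrus medial segment,left,frontal,0.0047,0.000564
Superior frontal gyrus medial segment,right,frontal,0.0047,0.000564
Middle frontal gyrus,left,frontal,0.0123,0.001476
Middle frontal gyrus,right,frontal,0.0123,0.001476
Inferior frontal gyrus pars opercularis,left,frontal,0.0027,0.000324
Inferior frontal gyrus pars opercularis,right,frontal,0.0027,0.000324
Inferior frontal gyrus pars triangularis,left,frontal,0.0026,0.000312
Inferior frontal gyrus pars triangularis,right,frontal,0.0026,0.000312
Inferior frontal gyrus pars orbitalis,left,frontal,0.0012,0.000144
Inferior frontal gyrus pars orbitalis,right,frontal,0.0012,0.000144
Precentral gyrus,left,frontal,0.0078,0.000936
Precentral gyrus,right,frontal,0.0078,0.000936
Precentral gyrus medial segment,left,frontal,0.0019,0.000228
Precentral gyrus medial segment,right,frontal,0.0019,0.000228
Medial frontal cortex,left,frontal,0.0014,0.000168
Medial frontal cortex,right,frontal,0.0014,0.000168
Anterior orbital gyrus,left,frontal,0.001,0.00012
Anterior orbital gyrus,right,frontal,0.001,0.00012
Lateral orbital gyrus,left,frontal,0.0014,0.000168
Lateral orbital gyrus,right,frontal,0.0014,0.000168
Medial orbital gyrus,left,frontal,0.0021,0.000252
Medial orbital gyrus,right,frontal,0.0021,0.000252
Posterior orbital gyrus,left,frontal,0.0015,0.00018
Posterior orbital gyrus,right,frontal,0.0015,0.00018
Gyrus rectus,left,frontal,0.0013,0.000156
Gyrus rectus,right,frontal,0.0013,0.000156
Supplementary motor cortex,left,frontal,0.0035,0.00042
Supplementary motor cortex,right,frontal,0.0035,0.00042
Frontal operculum,left,frontal,0.0012,0.000144
Frontal operculum,right,frontal,0.0012,0.000144
Frontal pole,left,frontal,0.0023,0.000276
Frontal pole,right,frontal,0.0023,0.000276
Postcentral gyrus,left,parietal,0.0064,0.000768
Postcentral gyrus,right,parietal,0.0064,0.000768
Postcentral gyrus medial segment,left,parietal,0.0011,0.000132
Postcentral gyrus medial segment,right,parietal,0.0011,0.000132
Superior parietal lobule,left,parietal,0.0067,0.000804
Superior parietal lobule,right,parietal,0.0067,0.000804
Supramarginal gyrus,left,parietal,0.0055,0.00066
Supramarginal gyrus,right,parietal,0.0055,0.00066
Angular gyrus,left,parietal,0.0061,0.000732
Angular gyrus,right,parietal,0.0061,0.000732
Precuneus,left,parietal,0.0067,0.000804
Precuneus,right,parietal,0.0067,0.000804
Paracentral lobule,left,parietal,0.0023,0.000276
Paracentral lobule,right,parietal,0.0023,0.000276
Parietal operculum,left,parietal,0.0013,0.000156
Parietal operculum,right,parietal,0.0013,0.000156
Central operculum,left,parietal,0.0024,0.000288
Central operculum,right,parietal,0.0024,0.000288
Calcarine cortex,left,occipital,0.0024,0.000288
Calcarine cortex,right,occipital,0.0024,0.000288
Cuneus,left,occipital,0.0028,0.000336
Cuneus,right,occipital,0.0028,0.000336
Lingual gyrus,left,occipital,0.0051,0.000612
Lingual gyrus,right,occipital,0.0051,0.000612
Occipital pole,left,occipital,0.0025,0.0003
Occipital pole,right,occipital,0.0025,0.0003
Superior occipital gyrus,left,occipital,0.0023,0.000276
Superior occipital gyrus,right,occipital,0.0023,0.000276
Middle occipital gyrus,left,occipital,0.0041,0.000492
Middle occipital gyrus,right,occipital,0.0041,0.000492
Inferior occipital gyrus,left,occipital,0.0027,0.000324
Inferior occipital gyrus,right,occipital,0.0027,0.000324
Occipital fusiform gyrus,left,occipital,0.0023,0.000276
Occipital fusiform gyrus,right,occipital,0.0023,0.000276
Anterior cingulate gyrus,left,cingulate,0.0031,0.000372
Anterior cingulate gyrus,right,cingulate,0.0031,0.000372
Middle cingulate gyrus,left,cingulate,0.0032,0.000384
Middle cingulate gyrus,right,cingulate,0.0032,0.000384
Posterior cingulate gyrus,left,cingulate,0.0026,0.000312
Posterior cingulate gyrus,right,cingulate,0.0026,0.000312
Subcallosal area,left,cingulate,0.0005,6e-05
Subcallosal area,right,cingulate,0.0005,6e-05
Anterior insula,left,insula,0.0027,0.000324
Anterior insula,right,insula,0.0027,0.000324
Posterior insula,left,insula,0.0014,0.000168
Posterior insula,right,insula,0.0014,0.000168
Caudate,left,basal ganglia,0.0024,0.000288
Caudate,right,basal ganglia,0.0024,0.000288
Putamen,left,basal ganglia,0.0027,0.000324
Putamen,right,basal ganglia,0.0027,0.000324
Pallidum,left,basal ganglia,0.0009,0.000108
Pallidum,right,basal ganglia,0.0009,0.000108
Accumbens area,left,basal ganglia,0.0003,3.6e-05
Accumbens area,right,basal ganglia,0.0003,3.6e-05
Basal forebrain,left,basal ganglia,0.0002,2.4e-05
Basal forebrain,right,basal ganglia,0.0002,2.4e-05
Claustrum,left,basal ganglia,0.0003,3.6e-05
Claustrum,right,basal ganglia,0.0003,3.6e-05
Thalamus proper,left,subcortical,0.0047,0.000564
Thalamus proper,right,subcortical,0.0047,0.000564
Ventral diencephalon,left,subcortical,0.0028,0.000336
Ventral diencephalon,right,subcortical,0.0028,0.000336
Brainstem,none,subcortical,0.0131,0.001572
Cerebellum exterior,left,subcortical,0.032,0.00384
Cerebellum exterior,right,subcortical,0.032,0.00384
Cerebellar vermal lobules I-V,none,subcortical,0.0027,0.000324
Cerebellar vermal lobules VI-VII,none,subcortical,0.0014,0.000168
Cerebellar vermal lobules VIII-X,none,subcortical,0.0022,0.000264
Septal nuclei,left,subcortical,0.0002,2.4e-05
Septal nuclei,right,subcortical,0.0002,2.4e-05
Lateral ventricle,left,ventricle/CSF,0.008,0.00096
Lateral ventricle,right,ventricle/CSF,0.008,0.00096
Third ventricle,none,ventricle/CSF,0.0007,8.4e-05
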