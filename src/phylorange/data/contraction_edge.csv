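species,CMCC-ESM2_SSP2-4.5,GISS-E2-1-G_SSP2-4.5,CMCC-ESM2_SSP3-7.0,GISS-E2-1-G_SSP3-7.0,EDGE
Centrolene altitudinalis,100.0,100.0,100.0,100.0,2.69
Centrolene ballux,58.2,45.2,89.4,41.4,2.38
Centrolene buckleyi,28.0,23.0,37.4,30.9,2.61
Centrolene condor,100.0,100.0,100.0,100.0,3.64
Centrolene geckoidea,55.3,42.7,54.9,41.4,4.09
Centrolene heloderma,65.3,46.2,72.8,61.9,2.72
Centrolene huilensis,-25.8,76.3,74.2,65.6,2.51
Centrolene lynchi,72.7,58.5,85.2,68.8,2.29
Centrolene medemi,100.0,16.2,100.0,-38.7,
Centrolene pipilata,100.0,-96.1,100.0,-123.0,3.29
Centrolene quindianum,70.7,-2.2,78.9,1.5,
Centrolene sanchezi,89.2,-74.3,75.7,-64.8,3.06
Centrolene solitaria,51.7,87.4,93.1,55.2,
Cochranella litoralis,27.8,-248.9,15.6,-256.7,3.47
Hyalinobatrachium duranti,100.0,100.0,100.0,100.0,3.64
Hyalinobatrachium esmeralda,20.3,-29.2,33.3,-25.1,3.14
Hyalinobatrachium guairarepanense,45.2,60.7,52.4,81.0,3.17
Hyalinobatrachium orientale,54.1,43.3,59.6,41.4,3.04
Ikakogi tayrona,48.0,77.6,42.4,80.0,3.71
Nymphargus anomalus,90.4,49.3,83.3,66.0,2.82
Nymphargus balionotus,100.0,84.6,100.0,89.2,3.43
Nymphargus bejaranoi,100.0,56.7,100.0,74.6,3.21
Nymphargus buenaventura,29.4,-21.6,21.5,19.6,3.03
Nymphargus cariticommatus,100.0,24.5,100.0,21.0,2.80
Nymphargus garciae,9.0,13.3,53.7,-67.6,3.07
Nymphargus lasgralarias,100.0,100.0,100.0,100.0,3.03
Nymphargus megistus,100.0,91.1,100.0,75.6,3.52
Nymphargus pluvialis,-87.0,-17.4,46.4,14.5,3.21
Nymphargus prasinus,100.0,100.0,100.0,100.0,
Nymphargus rosada,49.9,45.5,88.6,74.2,2.80
Nymphargus ruizi,7.4,-8.1,77.2,-20.4,
Nymphargus siren,21.2,8.4,24.5,3.9,2.88
Rulyrana adiazeta,3.3,22.1,13.1,36.9,3.08
Sachatamia electrops,-50.0,59.6,53.4,79.4,3.42
Sachatamia punctulata,-104.5,4.7,-35.0,-3.3,3.03
Vitreorana antisthenesi,94.3,71.7,88.6,41.4,3.07
Vitreorana helenae,100.0,100.0,100.0,100.0,3.45
Vitreorana parvula,40.3,49.4,53.9,54.6,3.07
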