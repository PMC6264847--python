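# Published reference dataset for Chroococcidiopsis cubana CCALA 043:
# proteins identified by LC-MS/MS and assigned to characteristic peaks of the
# intact-cell MALDI-TOF profile spectrum.  Masses in Da, calculated from
# sequence; *_nomet columns anticipate cleavage of the N-terminal methionine.
# peak_mz is the observed spectrum peak each protein was assigned to.
accession,name,mono_mass,avg_mass,mono_mass_nomet,avg_mass_nomet,peak_mz,pi
K9TYK3,Cytochrome b559 subunit beta,5059.7,5063.0,4928.6,4931.8,4933,10.8
K9TUG4,Photosystem one PsaX,5275.9,5279.2,5144.9,5148.0,5151,9.7
K9U763,Uncharacterized protein,5294.7,5298.1,5163.7,5166.9,5167,10.0
K9U1S7,CAB/ELIP/HLIP-like protein,6268.3,6272.4,6137.2,6141.2,6145,6.5
K9TXV0,CsbD family protein,6289.2,6292.9,6158.1,6161.7,6163,5.3
K9TWX6,50S ribosomal protein L32,6646.5,6650.6,6515.5,6519.4,6519,9.9
K9U0Q2,Uncharacterized protein,7009.7,7014.0,6878.6,6882.8,6879,4.4
K9U1N1,30S ribosomal protein S21,7160.1,7164.4,7029.0,7033.2,7034,11.9
K9U6A9,Uncharacterized protein,7958.2,7963.2,7827.1,7832.0,7837,4.8
K9TWD9,Molybdenum-pterin binding domain-containing protein,8181.1,8186.3,8050.1,8055.1,8057,8.9
K9U2Y0,Uncharacterized protein,8260.6,8265.9,8129.6,8134.7,8133,4.2
K9TYD6,30S ribosomal protein S18,8313.8,8318.9,8182.7,8187.7,8189,10.9
K9U6N7,Uncharacterized protein,8666.5,8672.0,8535.5,8540.8,8542,8.2
K9TTL0,50S ribosomal protein L29,8901.9,8907.3,8770.8,8776.1,8777,8.1
K9TX05,50S ribosomal protein L28,9132.9,9138.7,9001.8,9007.5,9008,10.9
K9TXI0,Uncharacterized protein,9621.8,9628.0,9490.8,9496.8,9492,6.1
K9U2M6,50S ribosomal protein L27,9987.3,9993.4,9856.3,9862.2,9864,11.3
K9TXE7,Glutaredoxin,10137.1,10143.6,10006.1,10012.4,10007,6.7
K9U5C3,Uncharacterized protein,10141.1,10147.4,10010.0,10016.2,10020,6.7
K9TSC9,30S ribosomal protein S19,10227.5,10233.9,10096.5,10102.7,10104,10.8
K9TYB6,30S ribosomal protein S15,10370.6,10376.9,10239.5,10245.7,10245,10.2
K9U6F7,Uncharacterized protein,10569.1,10576.0,10438.1,10444.8,10442,4.5
K9TTV4,30S ribosomal protein S20,11396.2,11403.3,11265.1,11272.1,11272,10.8
K9U7G6,Uncharacterized protein,11421.1,11428.3,11290.1,11297.1,11297,4.9
K9U809,Phosphoribosylformylglycinamidine synthase subunit PurS,11541.8,11549.3,11410.8,11418.1,11415,5.3
K9U2Y9,RNP-1 like RNA-binding protein,11601.7,11608.9,11470.7,11477.7,11477,6.4
K9TYP4,Uncharacterized protein,11780.0,11787.5,11649.0,11656.3,11654,5.3
K9U8M9,Glutaredoxin,11989.1,11996.8,11858.0,11865.6,11867,6.7
K9TWE1,30S ribosomal protein S6,12204.2,12211.9,12073.1,12080.7,12077,4.9
K9TYF8,Photosystem I reaction center subunit IV,13392.0,13400.1,13260.9,13268.9,13267,9.4
K9U057,50S ribosomal protein L7/L12,13676.2,13684.9,13545.2,13553.7,13552,4.7
K9U7R5,Plastocyanin,14616.6,14626.0,14485.6,14494.8,14489,9.1
K9U6S7,Photosystem I protein PsaD,15766.2,15776.1,15635.1,15644.9,15640,9.5
K9U8F2,Ribosome maturation factor RimP,17105.9,17116.5,16974.9,16985.3,16985,4.9
K9U3T4,Allophycocyanin beta subunit apoprotein,17703.1,17714.3,17572.0,17583.1,17584,5.4
K9TY88,Photosystem I reaction center protein PsaF subunit III,18399.6,18411.4,18268.6,18280.2,18281,7.8
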