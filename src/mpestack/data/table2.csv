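rank,combination,cost,auc,sensitivity,specificity
C1,PE.CEA,56.5,0.902,0.748,0.937
C2,PE.CA15-3,84,0.871,0.595,0.962
C3,PB.CEA+PE.CEA,113,0.899,0.766,0.913
C4,PE.CA19-9+PE.CEA,140.5,0.932,0.757,0.933
C5,PE.CA15-3+PE.CA19-9,168,0.927,0.721,0.957
C6,PB.CEA+PE.CA19-9+PE.CEA,197,0.932,0.748,0.923
C7,PE.CA15-3+PE.CA19-9+PE.CEA,224.5,0.942,0.775,0.942
C8,PB.CA15-3+PE.CA15-3+PE.CA19-9,252,0.925,0.739,0.952
C9,PB.CEA+PE.CA15-3+PE.CA19-9+PE.CEA,281,0.946,0.748,0.928
C10,PB.CA125+PE.CA15-3+PE.CA19-9+PE.CEA,308.5,0.944,0.757,0.957
C11,PB.CA125+PB.CA19-9+PE.CA15-3+PE.CA19-9,336,0.921,0.712,0.947
C12,PB.CA19-9+PB.CEA+PE.CA15-3+PE.CA19-9+PE.CEA,365,0.942,0.748,0.942
C13,PB.CA125+PE.CA125+PE.CA15-3+PE.CA19-9+PE.CEA,392.5,0.941,0.829,0.966
C14,PB.CA125+PB.CA15-3+PB.CA19-9+PE.CA15-3+PE.CA19-9,420,0.913,0.730,0.961
C15,PB.CA125+PB.CA15-3+PB.CEA+PE.CA125+PE.CA19-9+PE.CEA,449,0.938,0.775,0.952
C16,PB.CA125+PB.CA19-9+PE.CA125+PE.CA15-3+PE.CA19-9+PE.CEA,476.5,0.944,0.793,0.957
C17,PB.CA125+PB.CA15-3+PB.CA19-9+PE.CA125+PE.CA15-3+PE.CA19-9,504,0.910,0.712,0.947
C18,PB.CA125+PB.CA19-9+PB.CEA+PE.CA125+PE.CA15-3+PE.CA19-9+PE.CEA,533,0.940,0.802,0.957
C19,PB.CA125+PB.CA15-3+PB.CA19-9+PE.CA125+PE.CA15-3+PE.CA19-9+PE.CEA,560.5,0.939,0.820,0.942
C20,PB.CA125+PB.CA15-3+PB.CA19-9+PB.CEA+PE.CA125+PE.CA15-3+PE.CA19-9+PE.CEA,617,0.937,0.793,0.961
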