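region,sham_home,sham_expl,mcao_expl_ipsi,mcao_expl_contra
AcbSH/AcbC,290.8,481.3,517.8,578.9
ACCc,63.2,410.7,161.6,375.7
ACCr,64.0,415.6,219.2,387.3
AD,64.5,153.2,53.2,71.4
AGl,58.2,291.0,204.0,347.3
AM,55.9,213.0,136.8,169.2
ArcM/ArcLP,187.1,467.5,461.7,500.0
Au1,55.9,476.3,305.8,655.1
AV,34.7,105.9,75.4,101.9
BLA/CeM,257.1,374.0,265.2,361.4
CA1,5.2,56.8,38.3,54.5
CA3,4.9,34.8,30.7,33.2
CL/DEn,340.3,667.8,447.7,703.2
CPu,121.7,317.1,271.3,376.5
cRSP,109.3,683.3,471.2,833.6
CxA,213.8,1385.1,736.9,1155.6
DG,25.5,48.9,36.3,45.5
LEnt,53.2,213.6,109.8,167.4
LH/AHA,222.1,417.2,438.2,497.9
LS,32.4,217.3,200.2,225.9
MEnt,49.5,309.8,219.5,349.5
MG,34.4,112.1,69.5,78.8
MHb,105.3,170.3,138.8,145.5
MPA/MPOL/MPOM,177.3,456.6,364.6,468.4
MPT,194.4,497.5,385.4,460.8
Op,159.3,378.0,382.6,424.0
PaAP/PaPO,237.4,519.1,652.2,721.8
PAG,77.9,266.2,167.8,186.1
Pir,136.4,1128.3,296.7,1128.4
PRh,55.6,362.8,166.6,282.9
PV/PVA/PVP,316.2,832.2,722.0,761.0
RCh,203.8,413.1,393.5,351.5
RSGr,107.6,472.0,295.3,566.4
SuM,56.3,260.2,231.3,272.8
VDB,84.6,242.5,363.1,374.2
SO,650.5,703.1,490.1,365.9
Sch,2390.7,2091.3,2255.4,2781.4
IPAC,156.4,193.6,151.4,204.0
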