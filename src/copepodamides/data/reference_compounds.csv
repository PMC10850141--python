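scaffold,acyl,reported_mz,described_in,present_in,single_sample
dhCA,14:0,660.5,Grebner2019,B,False
dhCA,15:1,672.5,ThisStudy,F,False
dhCA,15:0,674.5,ThisStudy,B,False
dhCA,16:4,680.5,ThisStudy,M,False
dhCA,16:3,682.5,ThisStudy,M,False
dhCA,16:2,684.5,ThisStudy,B,False
dhCA,16:1,686.5,ThisStudy,B,False
dhCA,16:0,688.6,Grebner2019,B,False
dhCA,17:1,700.5,ThisStudy,F,False
dhCA,17:0,702.7,ThisStudy,F,False
dhCA,18:5,706.5,Grebner2019,M,False
dhCA,18:4,708.6,Grebner2019,B,False
dhCA,18:3,710.6,Grebner2019,B,False
dhCA,18:2,712.6,Grebner2019,B,False
dhCA,18:1,714.6,Grebner2019,B,False
dhCA,20:5,734.6,Grebner2019,B,False
dhCA,20:4,736.6,Grebner2019,F,False
dhCA,20:3,738.7,ThisStudy,F,False
dhCA,20:1,742.6,ThisStudy,M,False
dhCA,22:6,760.6,Grebner2019,B,False
dhCA,22:5,762.6,Grebner2019,F,False
CA,14:0,658.5,Grebner2019,M,False
CA,16:4,678.5,Grebner2019,M,True
CA,16:1,684.4,Grebner2019,M,False
CA,16:0,686.6,Grebner2019,M,False
CA,18:5,704.5,Grebner2019,M,False
CA,18:4,706.6,Grebner2019,M,False
CA,18:3,708.6,Grebner2019,M,False
CA,18:2,710.6,Grebner2019,M,False
CA,18:1,712.6,Grebner2019,M,False
CA,18:0,714.6,Grebner2019,M,False
CA,20:5,732.6,Grebner2019,M,False
CA,20:4,734.6,Grebner2019,M,False
CA,22:6,758.7,Grebner2019,M,False
CA,22:5,760.6,Grebner2019,M,False
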